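"""Core containers for polytomous item-response data and calibrated item banks.

The ordinal responses are stored on the instrument's own scale, category
codes ``1..K`` (``K = 5`` for a five-point Likert scale); missing entries are
``NaN``.  Item parameters live on the latent-trait (theta) metric of the
logistic graded response model with scaling constant ``D = 1``, i.e. the
boundary probability of scoring above category ``k`` is
``1 / (1 + exp(-a (theta - b_k)))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseMatrix",
    "ItemParameters",
    "ItemBank",
    "ThetaGrid",
    "CurveTable",
    "ValidationError",
    "read_responses",
    "read_bank",
    "write_bank",
    "load_default_bank",
]

_DEFAULT_BANK_RESOURCE = "promis_a_bank.json"


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass(frozen=True)
class ItemParameters:
    """One graded-response item: discrimination ``a`` and ordered thresholds.

    ``b`` holds the K-1 category thresholds on the theta metric; ``b[k]`` is
    the theta at which responding above category ``k+1`` is a coin flip.
    """

    item_id: str
    a: float
    b: tuple[float, ...]
    wording: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValidationError(f"item {self.item_id!r}: discrimination a must be positive, got {self.a}")
        b = tuple(float(x) for x in self.b)
        object.__setattr__(self, "b", b)
        if len(b) < 1 or not all(np.isfinite(b)):
            raise ValidationError(f"item {self.item_id!r}: thresholds must be finite, got {b}")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValidationError(f"item {self.item_id!r}: thresholds must be strictly increasing, got {b}")

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1

    @property
    def intervals(self) -> tuple[float, ...]:
        """Differences between adjacent thresholds, ``b[k+1] - b[k]``."""
        return tuple(b2 - b1 for b1, b2 in zip(self.b, self.b[1:]))


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of :class:`ItemParameters` sharing K categories."""

    items: tuple[ItemParameters, ...]
    K: int = 5
    metric: str = "logistic, D=1"
    name: str | None = None

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate item ids in bank: {dupes}")
        for it in items:
            if it.n_categories != self.K:
                raise ValidationError(
                    f"item {it.item_id!r} has {it.n_categories} categories, bank declares K={self.K}"
                )

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, key: int | str) -> ItemParameters:
        if isinstance(key, str):
            for it in self.items:
                if it.item_id == key:
                    return it
            raise KeyError(key)
        return self.items[key]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def subset(self, item_ids: Iterable[str]) -> "ItemBank":
        return ItemBank(items=tuple(self[i] for i in item_ids), K=self.K, metric=self.metric, name=self.name)

    def discriminations(self) -> np.ndarray:
        return np.array([it.a for it in self.items])

    def thresholds(self) -> np.ndarray:
        """(J, K-1) array of thresholds in bank order."""
        return np.array([it.b for it in self.items])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            row = {"item_id": it.item_id, "a": it.a}
            row.update({f"b{k + 1}": bk for k, bk in enumerate(it.b)})
            rows.append(row)
        return pd.DataFrame(rows).set_index("item_id")


@dataclass(frozen=True)
class ThetaGrid:
    """Quadrature grid over the latent trait: ordered nodes with prior masses."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2 or np.any(np.diff(nodes) <= 0):
            raise ValidationError("grid nodes must be a strictly increasing 1-d array")
        if weights.shape != nodes.shape or np.any(weights < 0):
            raise ValidationError("grid weights must be nonnegative and match nodes")
        if abs(weights.sum() - 1.0) > 1e-10:
            raise ValidationError("grid weights must sum to 1")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def normal(cls, n_nodes: int = 61, bounds: tuple[float, float] = (-6.0, 6.0),
               mean: float = 0.0, sd: float = 1.0) -> "ThetaGrid":
        """Equally spaced nodes with renormalized Normal(mean, sd^2) masses."""
        nodes = np.linspace(bounds[0], bounds[1], n_nodes)
        w = stats.norm.pdf(nodes, loc=mean, scale=sd)
        return cls(nodes=nodes, weights=w / w.sum())

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class CurveTable:
    """Values of named series evaluated on a theta grid (curves as tables)."""

    theta: np.ndarray
    columns: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta": self.theta, **self.columns})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ResponseMatrix:
    """n persons x J items of ordinal codes 1..K, plus person covariates.

    ``values`` is a float array with ``NaN`` marking missing responses;
    observed entries are integers in ``[1, K]``.  Covariates are categorical
    per-person columns (e.g. age group, gender) kept separate from the items.
    """

    values: np.ndarray
    item_ids: list[str]
    person_ids: list[str] | None = None
    covariates: pd.DataFrame | None = None
    K: int = 5

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValidationError("responses must be a 2-d person x item array")
        n, j = v.shape
        if n < 2 or j < 2:
            raise ValidationError(f"need at least 2 persons and 2 items, got {n} x {j}")
        if len(self.item_ids) != j:
            raise ValidationError("item_ids length must match number of columns")
        if len(set(self.item_ids)) != j:
            raise ValidationError("item_ids must be unique")
        obs = v[~np.isnan(v)]
        if obs.size and (np.any(obs != np.round(obs)) or obs.min() < 1 or obs.max() > self.K):
            raise ValidationError(f"observed codes must be integers in [1, {self.K}]")
        if self.person_ids is None:
            self.person_ids = [f"P{i + 1:05d}" for i in range(n)]
        if len(self.person_ids) != n:
            raise ValidationError("person_ids length must match number of rows")
        if self.covariates is not None:
            if len(self.covariates) != n:
                raise ValidationError("covariates must have one row per person")
            for col in self.covariates.columns:
                if self.covariates[col].dropna().nunique() < 1:
                    raise ValidationError(f"covariate {col!r} has no observed level")
        self.values = v

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def complete_rows(self) -> np.ndarray:
        """Boolean mask of persons with no missing responses."""
        return ~np.isnan(self.values).any(axis=1)

    def complete_cases(self) -> "ResponseMatrix":
        """Listwise-deleted copy (persons with any missing response dropped)."""
        mask = self.complete_rows()
        return ResponseMatrix(
            values=self.values[mask],
            item_ids=list(self.item_ids),
            person_ids=[p for p, m in zip(self.person_ids, mask) if m],
            covariates=None if self.covariates is None else self.covariates.loc[mask].reset_index(drop=True),
            K=self.K,
        )

    def to_frame(self, include_covariates: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.item_ids)
        df.insert(0, "person_id", self.person_ids)
        if include_covariates and self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df

    def to_csv(self, path: str | Path, missing_marker: str = "NA") -> None:
        df = self.to_frame()
        for c in self.item_ids:
            df[c] = df[c].astype("Int64")
        df.to_csv(path, index=False, na_rep=missing_marker)


def read_responses(
    path: str | Path,
    missing_marker: str = "NA",
    covariate_columns: Sequence[str] | None = None,
    covariate_prefix: str | None = None,
    person_id_column: str = "person_id",
    K: int = 5,
) -> ResponseMatrix:
    """Read a delimited person x item file into a :class:`ResponseMatrix`.

    The file must carry a header row; one person per row.  Covariate columns
    are separated from item columns either by an explicit list or by a shared
    name prefix.  Missing responses (``missing_marker``) are preserved, never
    imputed.
    """
    df = pd.read_csv(path, na_values=[missing_marker], keep_default_na=False, sep=None, engine="python")
    person_ids = None
    if person_id_column in df.columns:
        person_ids = df[person_id_column].astype(str).tolist()
        df = df.drop(columns=[person_id_column])
    cov_cols: list[str] = []
    if covariate_columns is not None:
        missing_cov = [c for c in covariate_columns if c not in df.columns]
        if missing_cov:
            raise ValidationError(f"covariate columns not in file: {missing_cov}")
        cov_cols = list(covariate_columns)
    elif covariate_prefix is not None:
        cov_cols = [c for c in df.columns if c.startswith(covariate_prefix)]
    item_cols = [c for c in df.columns if c not in cov_cols]
    if len(item_cols) != len(set(item_cols)):
        raise ValidationError("duplicate item column names in file")
    values = np.full((len(df), len(item_cols)), np.nan)
    for j, col in enumerate(item_cols):
        raw = df[col]
        for i, x in enumerate(raw):
            if pd.isna(x):
                continue
            try:
                xi = float(x)
            except (TypeError, ValueError):
                raise ValidationError(f"non-numeric code {x!r} at row {i + 1}, column {col!r}") from None
            if xi != round(xi) or not (1 <= xi <= K):
                raise ValidationError(f"code {x!r} out of range 1..{K} at row {i + 1}, column {col!r}")
            values[i, j] = xi
    covariates = df[cov_cols].copy() if cov_cols else None
    return ResponseMatrix(values=values, item_ids=item_cols, person_ids=person_ids, covariates=covariates, K=K)


def _bank_from_dict(payload: dict) -> ItemBank:
    if "items" not in payload:
        raise ValidationError("bank file missing 'items' key")
    items = []
    for entry in payload["items"]:
        item_id = entry.get("item_id")
        if item_id is None:
            raise ValidationError("bank entry missing 'item_id'")
        for key in ("a", "b"):
            if key not in entry:
                raise ValidationError(f"item {item_id!r}: missing {key!r}")
        items.append(
            ItemParameters(item_id=item_id, a=float(entry["a"]), b=tuple(entry["b"]), wording=entry.get("wording"))
        )
    return ItemBank(
        items=tuple(items),
        K=int(payload.get("K", len(items[0].b) + 1)),
        metric=payload.get("metric", "logistic, D=1"),
        name=payload.get("name"),
    )


def read_bank(path: str | Path) -> ItemBank:
    """Read an item bank from JSON (keys: item_id, wording, a, b, K, metric)."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"malformed bank file {path}: {exc}") from exc
    return _bank_from_dict(payload)


def write_bank(bank: ItemBank, path: str | Path) -> None:
    """Write a bank to JSON; round-trips all numeric fields exactly."""
    payload = {
        "name": bank.name,
        "K": bank.K,
        "metric": bank.metric,
        "items": [
            {"item_id": it.item_id, "wording": it.wording, "a": it.a, "b": list(it.b)}
            for it in bank.items
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_default_bank() -> ItemBank:
    """The packaged 23-item PROMIS-Cancer-Anxiety bank (Chinese calibration).

    Five response categories per item; parameters on the logistic D = 1
    metric with the latent trait standardized in the calibration sample.
    """
    ref = resources.files("grmkit").joinpath("data", _DEFAULT_BANK_RESOURCE)
    with ref.open() as fh:
        return _bank_from_dict(json.load(fh))
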