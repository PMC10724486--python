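"""Synthetic response data with the statistical structure the pipeline assumes.

The generative model is exactly the graded response model the calibrator
estimates: a latent trait ``theta ~ Normal(mean, sd^2)`` per person and,
conditional on theta, independent categorical draws from each item's category
probabilities.  Covariates are drawn independently of theta by default ("no
impact"); a group mean shift ("impact") and differential item functioning
(group-specific item parameters) are separate, explicit knobs so DIF studies
can distinguish the two.

``simulate_study`` produces the canonical study-shaped dataset: 1075
respondents answering the packaged 23-item five-category anxiety bank under a
standard-normal trait, with age 64.5/35.5, gender 38.0/62.0 and education
47.0/53.0 percent group splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ItemBank, ItemParameters, ResponseMatrix, ValidationError, load_default_bank
from .grm import boundary_prob

__all__ = ["SimulationConfig", "simulate_responses", "inject_dif", "simulate_study",
           "STUDY_COVARIATES"]

# Observed group frequencies of the calibration study (proportions per level)
STUDY_COVARIATES: dict[str, dict[str, float]] = {
    "age_group": {"18-59": 0.645, "60+": 0.355},
    "gender": {"male": 0.380, "female": 0.620},
    "education": {"junior_high_or_below": 0.470, "high_school_or_above": 0.530},
}


@dataclass(frozen=True)
class DIFSpec:
    """One injected DIF effect for the focal group of a grouping variable.

    ``uniform`` shifts all thresholds of the item by ``+magnitude`` theta
    units (the focal group finds every category harder to endorse);
    ``nonuniform`` multiplies the discrimination by ``1 + magnitude``.
    """

    item_id: str
    grouping: str
    kind: str = "uniform"  # or "nonuniform"
    magnitude: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "nonuniform"):
            raise ValidationError(f"unknown DIF kind {self.kind!r}")
        if not np.isfinite(self.magnitude):
            raise ValidationError("DIF magnitude must be finite")


@dataclass
class SimulationConfig:
    """Everything a simulation run needs; the seed is mandatory."""

    n: int
    seed: int
    bank: ItemBank | None = None
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    covariate_spec: dict[str, dict[str, float]] = field(default_factory=lambda: dict(STUDY_COVARIATES))
    dif_spec: list[DIFSpec] = field(default_factory=list)
    impact: dict[str, float] = field(default_factory=dict)  # grouping -> focal theta mean shift

    def __post_init__(self) -> None:
        for name, levels in self.covariate_spec.items():
            if abs(sum(levels.values()) - 1.0) > 1e-8:
                raise ValidationError(f"covariate {name!r}: proportions must sum to 1")


def inject_dif(bank: ItemBank, dif_spec: list[DIFSpec] | DIFSpec, grouping: str | None = None) -> ItemBank:
    """Focal-group bank with the requested DIF effects applied.

    The reference bank is untouched.  When ``grouping`` is given, only specs
    for that grouping variable are applied.
    """
    specs = [dif_spec] if isinstance(dif_spec, DIFSpec) else list(dif_spec)
    if grouping is not None:
        specs = [s for s in specs if s.grouping == grouping]
    items = {it.item_id: it for it in bank}
    for s in specs:
        if s.item_id not in items:
            raise ValidationError(f"DIF spec names unknown item {s.item_id!r}")
        it = items[s.item_id]
        if s.kind == "uniform":
            items[s.item_id] = ItemParameters(it.item_id, it.a,
                                              tuple(b + s.magnitude for b in it.b), it.wording)
        else:
            items[s.item_id] = ItemParameters(it.item_id, it.a * (1.0 + s.magnitude), it.b, it.wording)
    return ItemBank(items=tuple(items[i] for i in bank.item_ids), K=bank.K,
                    metric=bank.metric, name=bank.name)


def _draw_items(bank: ItemBank, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF categorical draws: X = 1 + #{k : u < P*_k(theta)}."""
    n = theta.size
    out = np.empty((n, len(bank)))
    u = rng.random((n, len(bank)))
    for j, item in enumerate(bank):
        pstar = boundary_prob(item, theta)  # (n, K-1), non-increasing in k
        out[:, j] = 1 + (u[:, [j]] < pstar).sum(axis=1)
    return out


def simulate_responses(config: SimulationConfig) -> tuple[ResponseMatrix, np.ndarray]:
    """Draw a response matrix from the graded response model.

    Returns the responses and the true thetas through a separate channel (the
    trait values are never written into the response data, so they cannot
    leak into pipeline tests).  Identical config and seed give identical
    output; all randomness flows from one named generator.
    """
    rng = np.random.default_rng(config.seed)
    bank = config.bank if config.bank is not None else load_default_bank()
    n = config.n

    covariates = None
    if config.covariate_spec:
        cols = {}
        for name, levels in config.covariate_spec.items():
            labels = list(levels)
            cols[name] = rng.choice(labels, size=n, p=[levels[l] for l in labels])
        covariates = pd.DataFrame(cols)

    theta = rng.normal(config.theta_mean, config.theta_sd, size=n)
    for grouping, shift in config.impact.items():
        focal = _focal_mask(covariates, grouping)
        theta[focal] += shift

    groupings_with_dif = {s.grouping for s in config.dif_spec}
    if groupings_with_dif:
        values = np.empty((n, len(bank)))
        # reference draws for everyone, then redraw focal persons' DIF items
        values[:] = _draw_items(bank, theta, rng)
        for grouping in sorted(groupings_with_dif):
            focal_bank = inject_dif(bank, config.dif_spec, grouping)
            focal = _focal_mask(covariates, grouping)
            dif_items = [s.item_id for s in config.dif_spec if s.grouping == grouping]
            cols = [bank.item_ids.index(i) for i in dif_items]
            redraw = _draw_items(focal_bank.subset(dif_items), theta[focal], rng)
            values[np.ix_(focal, cols)] = redraw
    else:
        values = _draw_items(bank, theta, rng)

    rm = ResponseMatrix(values=values, item_ids=list(bank.item_ids),
                        covariates=covariates, K=bank.K)
    return rm, theta


def _focal_mask(covariates: pd.DataFrame | None, grouping: str) -> np.ndarray:
    """Focal group = the second declared level of the grouping variable."""
    if covariates is None or grouping not in covariates.columns:
        raise ValidationError(f"grouping {grouping!r} is not a simulated covariate")
    levels = list(dict.fromkeys(STUDY_COVARIATES.get(grouping, {}))) or sorted(covariates[grouping].unique())
    focal_level = levels[-1]
    return (covariates[grouping] == focal_level).to_numpy()


def simulate_study(seed: int, n: int = 1075, dif_spec: list[DIFSpec] | None = None
                   ) -> tuple[ResponseMatrix, np.ndarray]:
    """The canonical study-shaped dataset (see module docstring)."""
    config = SimulationConfig(n=n, seed=seed, dif_spec=dif_spec or [])
    return simulate_responses(config)
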