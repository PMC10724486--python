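"""Preconditions for a unidimensional graded response model.

Three assumptions with explicit decision rules:

* **Unidimensionality** — principal component analysis on the Pearson
  correlation matrix of the raw ordinal scores, with the Kaiser-Meyer-Olkin
  sampling-adequacy statistic and Bartlett's sphericity test as entry checks.
  Verdict: first/second eigenvalue ratio greater than 3.
* **Local independence** — Yen's Q3: pairwise correlations of the residuals
  ``observed score - expected score`` under the fitted model at each person's
  EAP theta.  Verdict: every absolute off-diagonal Q3 below 0.70.
* **Monotonicity** — mean item score conditional on binned rest score (total
  minus the item); verdict: no bin-to-bin decrease beyond a noise tolerance.

KMO and Bartlett are computed from their textbook definitions (no dedicated
routine ships with the scientific stack used here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CurveTable, ItemBank, ResponseMatrix, ThetaGrid, ValidationError
from .information import eap_scores
from .grm import category_prob

__all__ = [
    "kmo_statistic",
    "bartlett_sphericity",
    "eigenvalue_ratio",
    "residual_correlations",
    "monotonicity_curves",
    "assumption_report",
    "AssumptionReport",
]


def _pearson_r(responses: ResponseMatrix | np.ndarray) -> tuple[np.ndarray, int]:
    v = responses.values if isinstance(responses, ResponseMatrix) else np.asarray(responses, dtype=float)
    v = v[~np.isnan(v).any(axis=1)]
    if v.shape[0] <= v.shape[1]:
        raise ValidationError("need more complete persons than items for correlation analysis")
    return np.corrcoef(v, rowvar=False), v.shape[0]


def kmo_statistic(responses: ResponseMatrix | np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    ``KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2)`` over i != j, where the
    ``q_ij`` are anti-image (partial) correlations from the inverse of the
    correlation matrix: ``q_ij = -inv(R)_ij / sqrt(inv(R)_ii inv(R)_jj)``.
    """
    r, _ = _pearson_r(responses)
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "correlation matrix is singular; consider removing redundant items") from exc
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    q = -rinv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = (r[off] ** 2).sum()
    q2 = (q[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def bartlett_sphericity(responses: ResponseMatrix | np.ndarray) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    ``chi2 = -(n - 1 - (2J + 5)/6) ln|R|`` with ``df = J(J-1)/2``; the
    p-value is the upper chi-square tail.
    """
    r, n = _pearson_r(responses)
    j = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValidationError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * j + 5) / 6.0) * logdet
    df = j * (j - 1) // 2
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def eigenvalue_ratio(responses: ResponseMatrix | np.ndarray,
                     threshold: float = 3.0) -> tuple[np.ndarray, float, bool]:
    """PCA roots of the Pearson correlation matrix of the raw ordinal scores.

    Returns (eigenvalues descending, lambda1/lambda2, verdict ratio > 3).
    """
    r, _ = _pearson_r(responses)
    eig = np.sort(np.linalg.eigvalsh(r))[::-1]
    ratio = float(eig[0] / eig[1])
    return eig, ratio, ratio > threshold


def residual_correlations(responses: ResponseMatrix, bank: ItemBank,
                          prior: ThetaGrid | None = None,
                          threshold: float = 0.70) -> tuple[pd.DataFrame, float, bool]:
    """Yen's Q3 residual correlations under a fitted graded response model.

    Per person and item, residual = observed score minus the model-expected
    score at the person's EAP theta; Q3 is the matrix of pairwise Pearson
    correlations of these residuals (diagonal set to NaN).  Verdict: maximum
    absolute off-diagonal value below ``threshold``.  Note Q3 has a small
    negative bias of order -1/(J-1) under local independence.
    """
    if prior is None:
        prior = ThetaGrid.normal()
    v = responses.values
    mask = ~np.isnan(v).any(axis=1)
    v = v[mask]
    theta = eap_scores(bank, v, prior)["eap_theta"].to_numpy()
    resid = np.empty_like(v)
    cats = np.arange(1, bank.K + 1)
    for j, item in enumerate(bank):
        p = category_prob(item, theta)  # (n, K)
        resid[:, j] = v[:, j] - p @ cats
    with np.errstate(invalid="ignore"):
        q3 = np.corrcoef(resid, rowvar=False)
    np.fill_diagonal(q3, np.nan)
    ids = responses.item_ids
    q3df = pd.DataFrame(q3, index=ids, columns=ids)
    max_abs = float(np.nanmax(np.abs(q3)))
    return q3df, max_abs, max_abs < threshold


def monotonicity_curves(responses: ResponseMatrix | np.ndarray, n_bins: int = 10,
                        min_bin_size: int = 30, decrease_tol: float = 0.05
                        ) -> tuple[dict[str, CurveTable], pd.Series]:
    """Mean item score conditional on binned rest score, with violation flags.

    The rest score (total minus the item) is cut into quantile bins; bins
    with fewer than ``min_bin_size`` persons are merged with a neighbor.  An
    item is flagged when the mean score drops by more than ``decrease_tol``
    between adjacent bins — a tolerance sized to absorb binomial noise at the
    minimum bin size.  A graded response model implies these curves are
    non-decreasing in the rest score.
    """
    v = responses.values if isinstance(responses, ResponseMatrix) else np.asarray(responses, dtype=float)
    v = v[~np.isnan(v).any(axis=1)]
    n, j = v.shape
    if n_bins < 3:
        raise ValidationError("need at least 3 bins")
    if n < n_bins * min_bin_size / 2:
        raise ValidationError(f"too few persons ({n}) to form {n_bins} bins of >= {min_bin_size}")
    ids = responses.item_ids if isinstance(responses, ResponseMatrix) else [f"item{k + 1}" for k in range(j)]
    total = v.sum(axis=1)
    curves: dict[str, CurveTable] = {}
    flags = {}
    for k in range(j):
        rest = total - v[:, k]
        # quantile bin edges; duplicates dropped for discrete rest scores
        edges = np.unique(np.quantile(rest, np.linspace(0, 1, n_bins + 1)))
        idx = np.clip(np.searchsorted(edges, rest, side="right") - 1, 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        # merge sparse bins into their left neighbor (first bin merges right)
        labels = np.arange(len(counts))
        for b in range(len(counts)):
            if counts[b] < min_bin_size:
                target = b - 1 if b > 0 else b + 1
                if 0 <= target < len(counts):
                    labels[labels == b] = labels[target]
        idx = labels[idx]
        uniq = np.unique(idx)
        means = np.array([v[idx == u, k].mean() for u in uniq])
        centers = np.array([rest[idx == u].mean() for u in uniq])
        order = np.argsort(centers)
        means, centers = means[order], centers[order]
        curves[ids[k]] = CurveTable(theta=centers, columns={
            "mean_score": means,
            "n": np.array([np.sum(idx == u) for u in uniq])[order].astype(float),
        })
        flags[ids[k]] = bool(np.any(np.diff(means) < -decrease_tol))
    return curves, pd.Series(flags, name="monotonicity_violation")


@dataclass
class AssumptionReport:
    """All three assumption checks with pass/fail verdicts."""

    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    eigenvalues: np.ndarray
    eigenvalue_ratio: float
    residual_corr: pd.DataFrame | None
    max_abs_q3: float | None
    monotonicity_flags: pd.Series
    monotonicity_curves: dict[str, CurveTable]
    verdicts: dict[str, bool] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "kmo": self.kmo,
            "bartlett": {"chi2": self.bartlett_chi2, "df": self.bartlett_df, "p": self.bartlett_p},
            "eigenvalue_ratio": self.eigenvalue_ratio,
            "max_abs_q3": self.max_abs_q3,
            "n_monotonicity_violations": int(self.monotonicity_flags.sum()),
            "verdicts": self.verdicts,
            "notes": self.notes,
        }


def assumption_report(responses: ResponseMatrix, bank: ItemBank | None = None,
                      prior: ThetaGrid | None = None, n_bins: int = 10,
                      ratio_threshold: float = 3.0, q3_threshold: float = 0.70) -> AssumptionReport:
    """Run the full assumption battery; Q3 is skipped when no bank is given."""
    kmo = kmo_statistic(responses)
    chi2, df, p = bartlett_sphericity(responses)
    eig, ratio, uni_ok = eigenvalue_ratio(responses, ratio_threshold)
    q3df = max_q3 = None
    li_ok = None
    if bank is not None:
        q3df, max_q3, li_ok = residual_correlations(responses, bank, prior, q3_threshold)
    curves, flags = monotonicity_curves(responses, n_bins=n_bins)
    verdicts = {
        "unidimensional": bool(uni_ok),
        "bartlett_significant": p < 0.05,
        "monotone": not bool(flags.any()),
    }
    if li_ok is not None:
        verdicts["locally_independent"] = bool(li_ok)
    return AssumptionReport(
        kmo=kmo, bartlett_chi2=chi2, bartlett_df=df, bartlett_p=p,
        eigenvalues=eig, eigenvalue_ratio=ratio,
        residual_corr=q3df, max_abs_q3=max_q3,
        monotonicity_flags=flags, monotonicity_curves=curves,
        verdicts=verdicts,
        notes={"residual_correlations": "Yen's Q3 on model residuals at EAP theta"},
    )
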