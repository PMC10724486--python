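"""Classical test-theory statistics: Cronbach's alpha, alpha-if-item-deleted,
and item-scale correlations.

All statistics use listwise deletion (persons with any missing response are
dropped; the count is reported) and the n-1 sample-variance convention.
Alpha is the raw covariance form, ``(J/(J-1)) (1 - sum(var_j)/var(total))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ResponseMatrix, ValidationError

__all__ = [
    "cronbach_alpha",
    "alpha_if_deleted",
    "item_rest_correlations",
    "reliability_report",
    "ReliabilityReport",
]


def _complete_values(responses: ResponseMatrix | np.ndarray) -> tuple[np.ndarray, int]:
    """Listwise-complete response array and the number of dropped rows."""
    v = responses.values if isinstance(responses, ResponseMatrix) else np.asarray(responses, dtype=float)
    mask = ~np.isnan(v).any(axis=1)
    return v[mask], int((~mask).sum())


def _alpha(v: np.ndarray) -> float:
    j = v.shape[1]
    if j < 2:
        raise ValidationError("Cronbach's alpha needs at least 2 items")
    total_var = v.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValidationError("total-score variance is zero; alpha undefined")
    return (j / (j - 1)) * (1.0 - v.var(axis=0, ddof=1).sum() / total_var)


def cronbach_alpha(responses: ResponseMatrix | np.ndarray) -> float:
    """Cronbach's alpha on listwise-complete rows (raw covariance form)."""
    v, _ = _complete_values(responses)
    if v.shape[0] < 3:
        raise ValidationError("too few complete rows for alpha")
    return float(_alpha(v))


def alpha_if_deleted(responses: ResponseMatrix | np.ndarray) -> pd.Series:
    """Alpha recomputed with each item removed in turn (J >= 3)."""
    v, _ = _complete_values(responses)
    j = v.shape[1]
    if j < 3:
        raise ValidationError("alpha-if-deleted needs at least 3 items")
    ids = responses.item_ids if isinstance(responses, ResponseMatrix) else [f"item{k + 1}" for k in range(j)]
    out = [_alpha(np.delete(v, k, axis=1)) for k in range(j)]
    return pd.Series(out, index=ids, name="alpha_if_deleted")


def item_rest_correlations(responses: ResponseMatrix | np.ndarray, corrected: bool = True) -> pd.Series:
    """Item-scale correlations on listwise-complete rows.

    By default each item is correlated with its rest score (total minus the
    item), the corrected convention that avoids inflation from the item's
    self-correlation.  ``corrected=False`` gives the raw item-total variant.
    Items with zero variance (or zero rest-score variance) are NaN.
    """
    v, _ = _complete_values(responses)
    j = v.shape[1]
    ids = responses.item_ids if isinstance(responses, ResponseMatrix) else [f"item{k + 1}" for k in range(j)]
    total = v.sum(axis=1)
    out = np.empty(j)
    for k in range(j):
        ref = total - v[:, k] if corrected else total
        if v[:, k].std(ddof=1) == 0 or ref.std(ddof=1) == 0:
            out[k] = np.nan
        else:
            out[k] = np.corrcoef(v[:, k], ref)[0, 1]
    return pd.Series(out, index=ids, name="item_rest_r" if corrected else "item_total_r")


@dataclass
class ReliabilityReport:
    alpha: float
    alpha_if_deleted: pd.Series
    item_rest_r: pd.Series
    n_used: int
    n_dropped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item_rest_r": self.item_rest_r,
                             "alpha_if_deleted": self.alpha_if_deleted})

    def summary(self) -> str:
        return (f"alpha={self.alpha:.4f} on n={self.n_used} complete rows "
                f"({self.n_dropped} dropped)")


def reliability_report(responses: ResponseMatrix | np.ndarray) -> ReliabilityReport:
    """Full internal-consistency report for a scale."""
    v, dropped = _complete_values(responses)
    return ReliabilityReport(
        alpha=cronbach_alpha(responses),
        alpha_if_deleted=alpha_if_deleted(responses),
        item_rest_r=item_rest_correlations(responses),
        n_used=v.shape[0],
        n_dropped=dropped,
    )
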