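"""Samejima graded response model: probabilities, marginal likelihood, and
marginal-maximum-likelihood EM calibration.

Model
-----
For an item with discrimination ``a`` and ordered thresholds ``b_1 < ... <
b_{K-1}``, the boundary ("operating characteristic") probability of scoring
above category ``k`` is logistic with D = 1:

    P*_k(theta) = 1 / (1 + exp(-a (theta - b_k)))

and category probabilities are the differences ``P_k = P*_{k-1} - P*_k``
with ``P*_0 = 1`` and ``P*_K = 0``.  Calibration integrates the latent trait
out over a fixed Normal(0, 1) quadrature prior (standard MML identification)
and alternates E-steps (posterior node weights per person) with per-item
Newton M-steps in slope/intercept form ``a * theta + d_k``, ``d_k = -a b_k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, log_expit, logit, logsumexp
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import (
    ItemBank,
    ItemParameters,
    ResponseMatrix,
    ThetaGrid,
    ValidationError,
)

__all__ = [
    "boundary_prob",
    "category_prob",
    "log_likelihood",
    "GradedResponseModel",
    "fit_grm",
    "screen_items",
    "CalibrationResult",
    "ScreeningReport",
]

A_CAP = 50.0  # Heywood-like divergence guard on the discrimination


def boundary_prob(item: ItemParameters, theta) -> np.ndarray:
    """P*_k(theta) for k = 1..K-1; shape (..., K-1), non-increasing in k."""
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(item.b)
    return expit(item.a * (theta[..., None] - b))


def category_prob(item: ItemParameters, theta) -> np.ndarray:
    """Category probabilities P_1..P_K at theta; shape (..., K), rows sum to 1."""
    pstar = boundary_prob(item, theta)
    ones = np.ones(pstar.shape[:-1] + (1,))
    zeros = np.zeros_like(ones)
    cum = np.concatenate([ones, pstar, zeros], axis=-1)
    return -np.diff(cum, axis=-1)


def _log_category_probs(eta: np.ndarray) -> np.ndarray:
    """Exact log category probabilities from boundary logits, saturation-safe.

    ``eta[..., k]`` is the logit of the k-th boundary probability (strictly
    decreasing in k).  Naive differencing of ``expit(eta)`` cancels to zero
    once ``eta`` exceeds ~37; the identity
    ``sigma(x) - sigma(y) = sigma(x) sigma(-y) (1 - exp(y - x))`` keeps every
    log probability finite for strictly ordered boundaries.
    """
    lo = log_expit(eta)          # log P*_k
    hi = log_expit(-eta)         # log (1 - P*_k)
    first = hi[..., :1]
    last = lo[..., -1:]
    if eta.shape[-1] == 1:
        return np.concatenate([first, last], axis=-1)
    with np.errstate(divide="ignore"):
        middle = (lo[..., :-1] + hi[..., 1:]
                  + np.log1p(-np.exp(np.minimum(eta[..., 1:] - eta[..., :-1], -1e-12))))
    return np.concatenate([first, middle, last], axis=-1)


def _log_category_prob_nodes(item: ItemParameters, nodes: np.ndarray) -> np.ndarray:
    """log P_k at quadrature nodes; shape (Q, K)."""
    eta = item.a * (nodes[:, None] - np.asarray(item.b))
    return _log_category_probs(eta)


def _person_node_loglik(bank: ItemBank, values: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """(n, Q) log-likelihood of each person's responses at each node.

    Missing entries contribute nothing (skipped in the product).
    """
    n = values.shape[0]
    out = np.zeros((n, nodes.size))
    for j, item in enumerate(bank):
        x = values[:, j]
        obs = ~np.isnan(x)
        if not obs.any():
            continue
        logp = _log_category_prob_nodes(item, nodes)  # (Q, K)
        out[obs] += logp[:, (x[obs] - 1).astype(int)].T
    return out


def log_likelihood(bank: ItemBank, responses: ResponseMatrix | np.ndarray, prior: ThetaGrid | None = None) -> float:
    """Marginal log-likelihood of the responses under the bank and theta prior.

    Computed in log space: sum over persons of
    ``log sum_q w_q prod_items P_{x_ij}(theta_q)``; never ``-inf`` through
    underflow for valid inputs.
    """
    values = responses.values if isinstance(responses, ResponseMatrix) else np.asarray(responses, dtype=float)
    if prior is None:
        prior = ThetaGrid.normal()
    ll = _person_node_loglik(bank, values, prior.nodes)
    return float(logsumexp(ll + np.log(prior.weights), axis=1).sum())


@dataclass
class ScreeningReport:
    """Item screening against the standard bank-quality rules.

    Rules: discrimination ``a > 0.50`` (else non-discriminating), every
    ``|b| < 10`` (else inappropriate for respondents), and adjacent-threshold
    intervals within ``[0.81, 5]`` (else category difficulty spacing suspect).
    """

    table: "pd.DataFrame"
    a_rule: float = 0.50
    b_rule: float = 10.0
    interval_low: float = 0.81
    interval_high: float = 5.0

    @property
    def flagged_intervals(self) -> list[tuple[str, str, float]]:
        out = []
        for item_id, row in self.table.iterrows():
            for name in (c for c in self.table.columns if c.startswith("interval_b")):
                val = row[name]
                if not (self.interval_low <= val <= self.interval_high):
                    out.append((item_id, name.replace("interval_", ""), float(val)))
        return out

    @property
    def all_pass(self) -> bool:
        return bool(self.table[["a_ok", "b_ok", "interval_ok"]].all().all())


def screen_items(bank: ItemBank, a_min: float = 0.50, b_abs_max: float = 10.0,
                 interval_range: tuple[float, float] = (0.81, 5.0)) -> ScreeningReport:
    """Apply the three parameter screening rules to every item in the bank.

    Intervals are exact differences of the stored thresholds (no rounding).
    """
    import pandas as pd

    rows = []
    for it in bank:
        intervals = it.intervals
        row = {
            "item_id": it.item_id,
            "a": it.a,
            "a_ok": it.a > a_min,
            "b_ok": all(abs(b) < b_abs_max for b in it.b),
        }
        for k, iv in enumerate(intervals):
            row[f"interval_b{k + 2}_b{k + 1}"] = iv
        row["interval_ok"] = all(interval_range[0] <= iv <= interval_range[1] for iv in intervals)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("item_id")
    return ScreeningReport(table=table, a_rule=a_min, b_rule=b_abs_max,
                           interval_low=interval_range[0], interval_high=interval_range[1])


@dataclass
class CalibrationResult:
    """Outcome of an MML-EM calibration run."""

    bank: ItemBank
    loglik: float
    trace: list[float]
    n_cycles: int
    converged: bool
    settings: dict
    se: "pd.DataFrame | None" = None
    category_maps: dict[str, dict[int, int]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _mstep_objective(params: np.ndarray, theta: np.ndarray, r: np.ndarray) -> float:
    """Expected complete-data log-likelihood for one item.

    params = (a, d_1..d_{K-1}); r is the (Q, K) expected count table.
    Returns -inf when the step makes any needed category probability
    non-positive (thresholds out of order), which step-halving rejects.
    """
    a, d = params[0], params[1:]
    if a <= 0 or np.any(np.diff(d) >= 0):
        return -np.inf
    logp = _log_category_probs(a * theta[:, None] + d[None, :])
    return float(np.sum(r * np.where(r > 0, logp, 0.0)))


def _mstep_gradient(params: np.ndarray, theta: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Analytic gradient of the M-step objective wrt (a, d_1..d_{K-1})."""
    a, d = params[0], params[1:]
    Km1 = d.size
    eta = a * theta[:, None] + d[None, :]
    pstar = expit(eta)
    s = pstar * (1 - pstar)
    p = np.exp(_log_category_probs(eta))
    # where r is zero the ratio's contribution is zero (0 * finite score)
    ratio = np.where(r > 0, r / np.clip(p, 1e-300, None), 0.0)  # (Q, K)
    # d/d eta_m: +s_m from category m+1, -s_m from category m (1-based cats)
    g_eta = s * (ratio[:, 1:] - ratio[:, :-1])  # (Q, K-1)
    grad = np.empty(Km1 + 1)
    grad[0] = float(np.sum(g_eta * theta[:, None]))
    grad[1:] = g_eta.sum(axis=0)
    return grad


def _feasible_lambda(params: np.ndarray, step: np.ndarray) -> float:
    """Largest step multiplier keeping a > 0 and the intercepts ordered.

    Both constraints are linear in lambda: ``a + lam * da > 0`` and
    ``(d_k - d_{k+1}) + lam * (dd_k - dd_{k+1}) > 0``.
    """
    vals = np.concatenate([[params[0]], -np.diff(params[1:])])
    coef = np.concatenate([[step[0]], -np.diff(step[1:])])
    lam = np.inf
    for v, c in zip(vals, coef):
        if c < 0:
            lam = min(lam, -v / c)
    return lam


def _newton_mstep(params: np.ndarray, theta: np.ndarray, r: np.ndarray,
                  max_iter: int = 25, tol: float = 1e-8) -> np.ndarray:
    """Per-item Newton ascent with feasibility-capped step-halving."""
    params = params.copy()
    f = _mstep_objective(params, theta, r)
    h = 1e-5
    for _ in range(max_iter):
        g = _mstep_gradient(params, theta, r)
        # Hessian by central differences of the analytic gradient
        H = np.empty((params.size, params.size))
        for i in range(params.size):
            e = np.zeros_like(params)
            e[i] = h
            H[:, i] = (_mstep_gradient(params + e, theta, r) - _mstep_gradient(params - e, theta, r)) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            newton = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            newton = None
        if newton is not None and np.dot(newton, g) <= 0:
            newton = None  # not an ascent direction
        gstep = g / max(1.0, np.abs(g).max())
        accepted = None
        for step in ([newton, gstep] if newton is not None else [gstep]):
            # never start the search on the infeasible side of the order cone
            lam = min(1.0, 0.9 * _feasible_lambda(params, step))
            for _ in range(30):
                cand = params + lam * step
                new_f = _mstep_objective(cand, theta, r)
                if np.isfinite(new_f) and new_f > f:
                    accepted = (cand, new_f, np.abs(lam * step).max())
                    break
                lam *= 0.5
            if accepted is not None:
                break
        if accepted is None:
            break  # no improving direction; params are at a Q-function optimum
        params, new_f, moved = accepted
        if new_f - f < tol and moved < 1e-6:
            f = new_f
            break
        f = new_f
    return params


def _collapse_empty_categories(values: np.ndarray, K: int) -> tuple[np.ndarray, list[dict[int, int]]]:
    """Remap observed codes so every item uses a dense 1..K_j range.

    Unobserved categories are merged with their neighbor toward the middle
    of the scale; the per-item remap (original -> collapsed) is returned.
    """
    values = values.copy()
    maps: list[dict[int, int]] = []
    mid = (K + 1) / 2
    for j in range(values.shape[1]):
        col = values[:, j]
        observed = sorted(set(col[~np.isnan(col)].astype(int)))
        remap: dict[int, int] = {}
        if len(observed) < 2:
            raise ValidationError(f"item column {j} has fewer than 2 observed categories")
        # assign each original category to the nearest observed category
        # toward the scale middle, then densify
        for k in range(1, K + 1):
            if k in observed:
                remap[k] = k
            else:
                side = [o for o in observed if (o > k if k < mid else o < k)]
                remap[k] = (min(side) if k < mid else max(side)) if side else (
                    min(observed, key=lambda o: abs(o - k)))
        dense = {o: i + 1 for i, o in enumerate(observed)}
        remap = {k: dense[remap[k]] for k in remap}
        obs_mask = ~np.isnan(col)
        values[obs_mask, j] = np.array([remap[int(x)] for x in col[obs_mask]])
        maps.append(remap)
    return values, maps


class GradedResponseModel(BaseEstimator, TransformerMixin):
    """Graded response model calibrated by marginal maximum likelihood EM.

    Scikit-learn style estimator: ``fit`` takes an ``(n_persons, n_items)``
    array of ordinal codes ``1..K`` (NaN = missing) or a
    :class:`~grmkit.data_model.ResponseMatrix`; ``transform`` returns EAP
    trait scores with posterior standard deviations.

    Parameters
    ----------
    n_categories : scale length K (categories coded 1..K).
    n_quadrature, theta_range : rectangular quadrature grid for the fixed
        Normal(0, 1) latent-trait prior (renormalized after truncation).
    tol : EM stop rule, max absolute parameter change between cycles.
    max_cycles : EM cycle cap; non-convergence yields ``converged_ = False``
        and a warning, never an exception.
    compute_se : if True, standard errors from the empirical cross-product
        of per-person score contributions are attached to the result.
    min_persons : refuse to calibrate below this sample size.

    Attributes
    ----------
    bank_ : calibrated :class:`~grmkit.data_model.ItemBank`.
    loglik_ : final marginal log-likelihood.
    trace_ : per-cycle marginal log-likelihood (non-decreasing, EM property).
    n_cycles_, converged_ : EM bookkeeping.
    result_ : full :class:`CalibrationResult`.
    """

    def __init__(self, n_categories: int = 5, n_quadrature: int = 61,
                 theta_range: tuple[float, float] = (-6.0, 6.0), tol: float = 1e-4,
                 max_cycles: int = 500, newton_iter: int = 25,
                 compute_se: bool = False, min_persons: int = 100):
        self.n_categories = n_categories
        self.n_quadrature = n_quadrature
        self.theta_range = theta_range
        self.tol = tol
        self.max_cycles = max_cycles
        self.newton_iter = newton_iter
        self.compute_se = compute_se
        self.min_persons = min_persons

    # -- helpers -----------------------------------------------------------
    def _coerce(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, ResponseMatrix):
            return X.values, list(X.item_ids)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-d (persons x items)")
        return X, [f"item{j + 1}" for j in range(X.shape[1])]

    def _start_values(self, values: np.ndarray, K_j: int, j: int) -> np.ndarray:
        """a = 1; d_k from the inverse logistic of marginal cumulative proportions."""
        col = values[:, j]
        col = col[~np.isnan(col)]
        d = np.empty(K_j - 1)
        for k in range(1, K_j):
            p_above = np.clip(np.mean(col > k), 1e-3, 1 - 1e-3)
            d[k - 1] = logit(p_above)
        # enforce strict decrease (ties possible in tiny samples)
        for k in range(1, d.size):
            if d[k] >= d[k - 1]:
                d[k] = d[k - 1] - 1e-3
        return np.concatenate([[1.0], d])

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y=None):
        values, item_ids = self._coerce(X)
        n, J = values.shape
        if n < self.min_persons:
            raise ValidationError(
                f"{n} persons is below the minimum of {self.min_persons} for stable calibration")
        K = self.n_categories
        values, cat_maps = _collapse_empty_categories(values, K)
        grid = ThetaGrid.normal(self.n_quadrature, self.theta_range)
        theta, logw = grid.nodes, np.log(grid.weights)
        Q = theta.size

        K_j = [int(np.nanmax(values[:, j])) for j in range(J)]
        params = [self._start_values(values, K_j[j], j) for j in range(J)]
        # response indicator tables: per item, (n_obs_idx, code) pairs
        obs_idx = [np.flatnonzero(~np.isnan(values[:, j])) for j in range(J)]
        codes = [(values[obs_idx[j], j] - 1).astype(int) for j in range(J)]

        flags: list[str] = []
        trace: list[float] = []
        converged = False
        cycle = 0
        for cycle in range(1, self.max_cycles + 1):
            # E-step: person x node posterior weights
            ll = np.zeros((n, Q))
            logp_items = []
            for j in range(J):
                a, d = params[j][0], params[j][1:]
                logp = _log_category_probs(a * theta[:, None] + d[None, :])
                logp_items.append(logp)
                ll[obs_idx[j]] += logp[:, codes[j]].T
            joint = ll + logw
            norm = logsumexp(joint, axis=1)
            trace.append(float(norm.sum()))
            post = np.exp(joint - norm[:, None])  # (n, Q)

            # M-step: per-item expected count tables and Newton updates
            max_change = 0.0
            for j in range(J):
                r = np.zeros((Q, K_j[j]))
                pj = post[obs_idx[j]]
                np.add.at(r.T, codes[j], pj)
                new = _newton_mstep(params[j], theta, r, max_iter=self.newton_iter)
                if new[0] > A_CAP:
                    flags.append(f"{item_ids[j]}: discrimination capped at {A_CAP}")
                    new = new.copy()
                    new[0] = A_CAP
                max_change = max(max_change, float(np.abs(new - params[j]).max()))
                params[j] = new
            if max_change < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"EM did not converge in {self.max_cycles} cycles "
                          f"(last max parameter change {max_change:.2e})", stacklevel=2)

        items = []
        for j in range(J):
            a, d = params[j][0], params[j][1:]
            b = np.sort(-d / a)
            items.append(ItemParameters(item_id=item_ids[j], a=float(a), b=tuple(b)))
        Kb = K_j[0] if len(set(K_j)) == 1 else K
        if len(set(K_j)) > 1:
            flags.append("items differ in observed category count after collapsing; "
                         "bank K reflects the declared scale")
            # pad is not meaningful; keep per-item categories via b length
            bank = ItemBank.__new__(ItemBank)  # bypass shared-K invariant
            object.__setattr__(bank, "items", tuple(items))
            object.__setattr__(bank, "K", K)
            object.__setattr__(bank, "metric", "logistic, D=1")
            object.__setattr__(bank, "name", "calibrated")
        else:
            bank = ItemBank(items=tuple(items), K=Kb, metric="logistic, D=1", name="calibrated")

        final_ll = trace[-1]
        settings = {
            "n_quadrature": self.n_quadrature, "theta_range": list(self.theta_range),
            "tol": self.tol, "max_cycles": self.max_cycles, "newton_iter": self.newton_iter,
            "prior": "normal(0,1)", "metric": "logistic, D=1",
        }
        se = self._empirical_se(bank, values, grid) if self.compute_se else None
        self.bank_ = bank
        self.grid_ = grid
        self.loglik_ = final_ll
        self.trace_ = trace
        self.n_cycles_ = cycle
        self.converged_ = converged
        self.n_features_in_ = J
        self.result_ = CalibrationResult(
            bank=bank, loglik=final_ll, trace=trace, n_cycles=cycle, converged=converged,
            settings=settings, se=se,
            category_maps={item_ids[j]: cat_maps[j] for j in range(J)
                           if any(k != v for k, v in cat_maps[j].items())},
            flags=flags,
        )
        return self

    def _empirical_se(self, bank: ItemBank, values: np.ndarray, grid: ThetaGrid):
        """SEs from the empirical cross-product of per-person score vectors,
        with scores obtained by central differences of the marginal loglik."""
        import pandas as pd

        def person_loglik(b: ItemBank) -> np.ndarray:
            ll = _person_node_loglik(b, values, grid.nodes)
            return logsumexp(ll + np.log(grid.weights), axis=1)

        names, scores = [], []
        h = 1e-4
        for j, it in enumerate(bank):
            for p_idx in range(len(it.b) + 1):
                def perturbed(delta: float) -> ItemBank:
                    items = list(bank.items)
                    if p_idx == 0:
                        items[j] = ItemParameters(it.item_id, it.a + delta, it.b, it.wording)
                    else:
                        b = list(it.b)
                        b[p_idx - 1] += delta
                        items[j] = ItemParameters(it.item_id, it.a, tuple(b), it.wording)
                    nb = ItemBank.__new__(ItemBank)
                    object.__setattr__(nb, "items", tuple(items))
                    object.__setattr__(nb, "K", bank.K)
                    object.__setattr__(nb, "metric", bank.metric)
                    object.__setattr__(nb, "name", bank.name)
                    return nb

                scores.append((person_loglik(perturbed(h)) - person_loglik(perturbed(-h))) / (2 * h))
                names.append(f"{it.item_id}:{'a' if p_idx == 0 else f'b{p_idx}'}")
        S = np.column_stack(scores)
        info = S.T @ S
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(len(names), np.nan)
        return pd.Series(se, index=names, name="se").to_frame()

    def transform(self, X) -> np.ndarray:
        """EAP trait scores: columns (eap_theta, posterior_sd)."""
        from .information import eap_scores

        values, _ = self._coerce(X)
        scores = eap_scores(self.bank_, values, self.grid_)
        return scores[["eap_theta", "posterior_sd"]].to_numpy()

    def score(self, X, y=None) -> float:
        """Mean marginal log-likelihood per person (model comparison utility)."""
        values, _ = self._coerce(X)
        return log_likelihood(self.bank_, values, self.grid_) / values.shape[0]


def fit_grm(responses: ResponseMatrix | np.ndarray, prior: ThetaGrid | None = None,
            tol: float = 1e-4, max_cycles: int = 500, compute_se: bool = False,
            min_persons: int = 100) -> CalibrationResult:
    """Calibrate a graded response model; thin wrapper over
    :class:`GradedResponseModel`."""
    kwargs = {}
    if prior is not None:
        kwargs["n_quadrature"] = len(prior)
        kwargs["theta_range"] = (float(prior.nodes[0]), float(prior.nodes[-1]))
    K = responses.K if isinstance(responses, ResponseMatrix) else int(np.nanmax(np.asarray(responses, dtype=float)))
    model = GradedResponseModel(n_categories=K, tol=tol, max_cycles=max_cycles,
                                compute_se=compute_se, min_persons=min_persons, **kwargs)
    model.fit(responses)
    return model.result_
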