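"""Limited-information model fit for ordinal item response models.

The M2 statistic compares observed and model-implied univariate and
bivariate category margins (categories 2..K per item, so the moments are
linearly independent).  With ``r = p_obs - p_model`` the statistic is

    M2 = n * r' C r,   C = Xi^-1 - Xi^-1 D (D' Xi^-1 D)^-1 D' Xi^-1

where ``Xi`` is the model-implied asymptotic covariance of the sample
margins and ``D`` the Jacobian of the model margins with respect to the free
item parameters.  Under a correctly specified model M2 is asymptotically
chi-square with df = n_moments - n_parameters, which yields

    RMSEA = sqrt(max(M2 - df, 0) / (df (n - 1)))

and incremental indices against the independence (zero-association) baseline
with the same observed univariate margins:

    CFI = 1 - max(M2 - df, 0) / max(M2_B - df_B, M2 - df, 0)
    TLI = (M2_B/df_B - M2/df) / (M2_B/df_B - 1)   (reported unclipped).

Everything is assembled from per-item category-probability tables on a
quadrature grid, so the same machinery serves the fitted response model
(probabilities integrated over the trait prior) and the baseline (a
one-node "grid" holding the observed margins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .data_model import ItemBank, ResponseMatrix, ThetaGrid, ValidationError
from .grm import boundary_prob

__all__ = ["fit_indices", "FitIndices", "m2_statistic"]


@dataclass
class FitIndices:
    m2: float
    df: int
    p_value: float
    rmsea: float
    cfi: float
    tli: float
    m2_baseline: float
    df_baseline: int
    n: int
    note: str = ""

    def summary(self) -> dict:
        return {"M2": self.m2, "df": self.df, "p": self.p_value, "rmsea": self.rmsea,
                "cfi": self.cfi, "tli": self.tli, "note": self.note}


# ---------------------------------------------------------------------------
# generic moment machinery: items are (Q, K_i) probability tables + Jacobians

def _moment_index(Ks: list[int]) -> tuple[list[slice], dict[tuple[int, int], slice], int]:
    uni, biv = [], {}
    pos = 0
    for K in Ks:
        uni.append(slice(pos, pos + K - 1))
        pos += K - 1
    J = len(Ks)
    for i in range(J):
        for j in range(i + 1, J):
            size = (Ks[i] - 1) * (Ks[j] - 1)
            biv[(i, j)] = slice(pos, pos + size)
            pos += size
    return uni, biv, pos


def _model_moments(P: list[np.ndarray], w: np.ndarray) -> np.ndarray:
    uni, biv, m = _moment_index([p.shape[1] for p in P])
    pi = np.empty(m)
    for i, sl in enumerate(uni):
        pi[sl] = w @ P[i][:, 1:]
    for (i, j), sl in biv.items():
        pi[sl] = np.einsum("q,qk,ql->kl", w, P[i][:, 1:], P[j][:, 1:]).ravel()
    return pi


def _xi_matrix(P: list[np.ndarray], w: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Model-implied covariance of the sample moment vector.

    Start from the local-independence factorization integrated over the grid,
    then correct every moment pair that shares an item (where the product of
    category indicators collapses by the delta rule).
    """
    Ks = [p.shape[1] for p in P]
    uni, biv, m = _moment_index(Ks)
    J = len(P)
    M = np.empty((m, P[0].shape[0]))
    for i, sl in enumerate(uni):
        M[sl] = P[i][:, 1:].T
    for (i, j), sl in biv.items():
        M[sl] = np.einsum("qk,ql->klq", P[i][:, 1:], P[j][:, 1:]).reshape(sl.stop - sl.start, -1)
    xi = (M * w) @ M.T

    # G_i[q] = diag(P_i) - P_i P_i' on categories 2..K (the delta-rule correction)
    G = []
    for i in range(J):
        p1 = P[i][:, 1:]
        g = -np.einsum("qk,ql->qkl", p1, p1)
        kk = np.arange(Ks[i] - 1)
        g[:, kk, kk] += p1
        G.append(g)

    # univariate x univariate, same item
    for i in range(J):
        xi[uni[i], uni[i]] += np.einsum("q,qkl->kl", w, G[i])

    # univariate (item i) x bivariate (pair containing i)
    for (i, j), sl in biv.items():
        ni, nj = Ks[i] - 1, Ks[j] - 1
        c_i = np.einsum("q,qkm,ql->kml", w, G[i], P[j][:, 1:]).reshape(ni, ni * nj)
        xi[uni[i], sl] += c_i
        xi[sl, uni[i]] += c_i.T
        c_j = np.einsum("q,qk,qlm->klm", w, P[i][:, 1:], G[j]).reshape(ni * nj, nj)
        # rows are the bivariate index (k,l); columns the univariate l'
        xi[sl, uni[j]] += c_j
        xi[uni[j], sl] += c_j.T

    # bivariate x bivariate, identical pair
    for (i, j), sl in biv.items():
        ni, nj = Ks[i] - 1, Ks[j] - 1
        sub = np.einsum("q,qk,qm,ql,qn->klmn", w, P[i][:, 1:], P[i][:, 1:],
                        P[j][:, 1:], P[j][:, 1:])
        block = -sub.reshape(ni * nj, ni * nj)
        block[np.arange(ni * nj), np.arange(ni * nj)] += pi[sl]
        xi[sl, sl] += block

    # bivariate x bivariate, exactly one shared item
    pairs = list(biv)
    by_item: dict[int, list[tuple[int, int]]] = {}
    for pr in pairs:
        for it in pr:
            by_item.setdefault(it, []).append(pr)
    for shared, prs in by_item.items():
        for x in range(len(prs)):
            for yz in range(x + 1, len(prs)):
                pa, pb = prs[x], prs[yz]
                oa = pa[0] if pa[1] == shared else pa[1]
                ob = pb[0] if pb[1] == shared else pb[1]
                if oa == ob:
                    continue  # identical pair handled above
                corr = np.einsum("q,qkm,ql,qn->klmn", w, G[shared],
                                 P[oa][:, 1:], P[ob][:, 1:])
                # reorder axes to each pair's stored (first, second) convention
                a_ax = (0, 1) if pa[0] == shared else (1, 0)
                b_ax = (2, 3) if pb[0] == shared else (3, 2)
                blk = corr.transpose(*a_ax, *b_ax)
                na = (Ks[pa[0]] - 1) * (Ks[pa[1]] - 1)
                nb = (Ks[pb[0]] - 1) * (Ks[pb[1]] - 1)
                blk = blk.reshape(na, nb)
                xi[biv[pa], biv[pb]] += blk
                xi[biv[pb], biv[pa]] += blk.T
    xi -= np.outer(pi, pi)
    return xi


def _delta_matrix(P: list[np.ndarray], dP: list[np.ndarray], w: np.ndarray) -> np.ndarray:
    """Jacobian of the model moments wrt the stacked item parameters."""
    Ks = [p.shape[1] for p in P]
    uni, biv, m = _moment_index(Ks)
    q_sizes = [d.shape[2] for d in dP]
    offsets = np.concatenate([[0], np.cumsum(q_sizes)])
    delta = np.zeros((m, offsets[-1]))
    for i, sl in enumerate(uni):
        delta[sl, offsets[i]:offsets[i + 1]] = np.einsum("q,qkp->kp", w, dP[i][:, 1:, :])
    for (i, j), sl in biv.items():
        di = np.einsum("q,qkp,ql->klp", w, dP[i][:, 1:, :], P[j][:, 1:])
        dj = np.einsum("q,qk,qlp->klp", w, P[i][:, 1:], dP[j][:, 1:, :])
        size = sl.stop - sl.start
        delta[sl, offsets[i]:offsets[i + 1]] = di.reshape(size, -1)
        delta[sl, offsets[j]:offsets[j + 1]] = dj.reshape(size, -1)
    return delta


def _observed_moments(values: np.ndarray, Ks: list[int]) -> tuple[np.ndarray, int]:
    v = values[~np.isnan(values).any(axis=1)].astype(int)
    n = v.shape[0]
    J = v.shape[1]
    uni, biv, m = _moment_index(Ks)
    # one-hot for categories 2..K of each item
    Z = [np.equal(v[:, [i]], np.arange(2, Ks[i] + 1)).astype(float) for i in range(J)]
    p = np.empty(m)
    for i, sl in enumerate(uni):
        p[sl] = Z[i].mean(axis=0)
    for (i, j), sl in biv.items():
        p[sl] = (Z[i].T @ Z[j]).ravel() / n
    return p, n


def _grm_tables(bank: ItemBank, grid: ThetaGrid) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-item category probabilities and parameter Jacobians at the nodes."""
    P, dP = [], []
    th = grid.nodes
    for it in bank:
        pstar = boundary_prob(it, th)  # (Q, K-1)
        s = pstar * (1 - pstar)
        Q, Km1 = pstar.shape
        pad = np.zeros((Q, 1))
        cum = np.concatenate([np.ones((Q, 1)), pstar, pad], axis=1)
        P.append(-np.diff(cum, axis=1))
        # params (a, b_1..b_{K-1}); boundary derivs, then difference
        dstar = np.zeros((Q, Km1, Km1 + 1))
        dstar[:, :, 0] = (th[:, None] - np.array(it.b)) * s
        for k in range(Km1):
            dstar[:, k, k + 1] = -it.a * s[:, k]
        dcum = np.concatenate([np.zeros((Q, 1, Km1 + 1)), dstar, np.zeros((Q, 1, Km1 + 1))], axis=1)
        dP.append(-np.diff(dcum, axis=1))
    return P, dP


def m2_statistic(P: list[np.ndarray], dP: list[np.ndarray], w: np.ndarray,
                 p_obs: np.ndarray, n: int) -> tuple[float, int]:
    """M2 for arbitrary per-item probability tables (see module docstring)."""
    pi = _model_moments(P, w)
    xi = _xi_matrix(P, w, pi)
    delta = _delta_matrix(P, dP, w)
    r = p_obs - pi
    try:
        cf = linalg.cho_factor(xi)
    except linalg.LinAlgError:
        # tiny ridge for numerically semidefinite cases (sparse extreme cells)
        cf = linalg.cho_factor(xi + 1e-10 * np.eye(xi.shape[0]))
    xir = linalg.cho_solve(cf, r)
    xid = linalg.cho_solve(cf, delta)
    dtxid = delta.T @ xid
    dtxir = delta.T @ xir
    # least squares: tolerant of the near-singular information that arises
    # when some margins carry almost no parameter information
    inner = np.linalg.lstsq(dtxid, dtxir, rcond=None)[0]
    m2 = n * float(r @ xir - dtxir @ inner)
    df = p_obs.size - delta.shape[1]
    return max(m2, 0.0), df


def fit_indices(responses: ResponseMatrix | np.ndarray, bank: ItemBank,
                prior: ThetaGrid | None = None) -> FitIndices:
    """M2-based RMSEA, CFI and TLI for a calibrated graded response model.

    Uses complete response rows; warns (via the note field) when bivariate
    margins are sparsely populated.
    """
    values = responses.values if isinstance(responses, ResponseMatrix) else np.asarray(responses, dtype=float)
    if prior is None:
        prior = ThetaGrid.normal()
    Ks = [it.n_categories for it in bank]
    p_obs, n = _observed_moments(values, Ks)
    note = ""
    if n * min(p_obs.min(), 1e9) < 1:  # cells with zero observed count
        note = "some bivariate margins are empty; M2 may be unstable"

    P, dP = _grm_tables(bank, prior)
    m2, df = m2_statistic(P, dP, prior.weights, p_obs, n)
    if df <= 0:
        raise ValidationError("non-positive degrees of freedom for M2")

    # independence baseline: one-node tables holding the observed margins,
    # free parameters = the univariate category probabilities
    uni, _, _ = _moment_index(Ks)
    P0, dP0 = [], []
    for i, K in enumerate(Ks):
        pk = np.concatenate([[1 - p_obs[uni[i]].sum()], p_obs[uni[i]]])
        P0.append(pk[None, :])
        d = np.zeros((1, K, K - 1))
        d[0, 0, :] = -1.0
        d[0, 1:, :] = np.eye(K - 1)
        dP0.append(d)
    m2_b, df_b = m2_statistic(P0, dP0, np.ones(1), p_obs, n)

    rmsea = float(np.sqrt(max(m2 - df, 0.0) / (df * (n - 1))))
    denom = max(m2_b - df_b, m2 - df, 0.0)
    cfi = 1.0 - (max(m2 - df, 0.0) / denom if denom > 0 else 0.0)
    ratio_b = m2_b / df_b
    tli = (ratio_b - m2 / df) / (ratio_b - 1.0) if ratio_b != 1.0 else 1.0
    if tli > 1.0:
        note = (note + "; " if note else "") + "TLI above 1 reported unclipped"
    return FitIndices(m2=m2, df=df, p_value=float(stats.chi2.sf(m2, df)), rmsea=rmsea,
                      cfi=float(cfi), tli=float(tli), m2_baseline=m2_b, df_baseline=df_b,
                      n=n, note=note)
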