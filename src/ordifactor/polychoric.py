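"""Two-stage polychoric estimation with asymptotic covariance.

Stage one estimates each item's thresholds from its univariate margin
(tau = Phi^-1 of the cumulative proportions). Stage two estimates each
pairwise polychoric correlation by maximising the bivariate-normal
multinomial likelihood of the pair's contingency table with the
thresholds held fixed — the standard two-step estimator behind
categorical SEM. Missing data are handled pairwise-present.

The asymptotic covariance of the stacked (thresholds, correlations)
vector is obtained from the stacked estimating equations: if theta-hat
solves sum_i g_i(theta) = 0, then acov = A^-1 B A^-T / n with
A = -E[dg/dtheta] and B = E[g g']. B is computed from per-person score
contributions (so pairwise missingness and all cross-pair dependence is
captured empirically); A is block lower-triangular because threshold
equations do not involve the correlations. The diagonal of this matrix
is the DWLS weight; the full matrix feeds the mean-and-variance
adjusted test statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from ._bvn import cell_probs, cell_probs_drho
from .item_prep import MISSING, OrdinalItemMatrix

__all__ = [
    "PolychoricSummary",
    "estimate_thresholds",
    "estimate_polychoric_pair",
    "polychoric_matrix",
]

RHO_BOUND = 0.999


@dataclass
class PolychoricSummary:
    items: list[str]
    n_categories: list[int]
    thresholds: list[np.ndarray]          # per item, length K_j - 1
    R: np.ndarray                         # polychoric correlations (raw)
    R_pd: np.ndarray                      # positive-definite repaired copy
    n_pairwise: np.ndarray                # complete pairs per (j, k)
    n: int                                # persons in the dataset
    acov_full: np.ndarray                 # stacked (thresholds, corrs)
    acov_diag: np.ndarray

    @property
    def p(self) -> int:
        return len(self.items)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        p = self.p
        return [(j, k) for j in range(p) for k in range(j + 1, p)]

    @property
    def n_thresh(self) -> int:
        return sum(len(t) for t in self.thresholds)

    def stat_vector(self) -> np.ndarray:
        """Sample statistics: thresholds item-major, then correlations
        in (j, k) j < k row-major order."""
        taus = np.concatenate(self.thresholds) if self.thresholds else np.empty(0)
        rhos = np.array([self.R[j, k] for j, k in self.pairs])
        return np.concatenate([taus, rhos])

    def to_frames(self) -> dict[str, pd.DataFrame]:
        rows = []
        for it, t in zip(self.items, self.thresholds):
            for k, v in enumerate(t):
                rows.append({"item": it, "threshold": k + 1, "tau": v})
        return {
            "R": pd.DataFrame(self.R, index=self.items, columns=self.items),
            "thresholds": pd.DataFrame(rows),
            "n_pairwise": pd.DataFrame(self.n_pairwise, index=self.items,
                                       columns=self.items),
        }


def estimate_thresholds(counts) -> np.ndarray:
    """Thresholds from univariate category counts:
    tau_k = Phi^-1(cumulative proportion through category k)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0 or np.any(counts < 0):
        raise ValueError("counts must be non-negative with positive total")
    if np.any(counts == 0):
        raise ValueError(
            "empty category in counts; merge sparse categories first "
            "(merge_sparse_categories)")
    cum = np.cumsum(counts) / counts.sum()
    return ndtri(cum[:-1])


def _pair_nll(table, t1, t2):
    def nll(rho):
        p = cell_probs(t1, t2, rho)
        return -float(np.sum(table * np.log(p)))
    return nll


def estimate_polychoric_pair(table, thresholds_j, thresholds_k):
    """ML polychoric correlation for one pair with fixed thresholds.

    Returns ``(rho, avar)`` where ``avar`` is the inverse observed
    information of the pair likelihood at the optimum.
    """
    table = np.asarray(table, dtype=float)
    nll = _pair_nll(table, thresholds_j, thresholds_k)
    res = minimize_scalar(nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": 1e-9})
    rho = float(res.x)
    if abs(rho) >= RHO_BOUND - 1e-6:
        warnings.warn("polychoric estimate at boundary; clamped to +/-0.999 "
                      "(near-perfect association)")
        rho = np.sign(rho) * RHO_BOUND
    h = 1e-4
    d2 = (nll(rho + h) - 2.0 * nll(rho) + nll(rho - h)) / h**2
    avar = 1.0 / d2 if d2 > 0 else np.inf
    return rho, avar


def _pair_table(x, y, kx, ky):
    ok = (x != MISSING) & (y != MISSING)
    t = np.zeros((kx, ky))
    np.add.at(t, (x[ok], y[ok]), 1.0)
    return t, int(ok.sum())


def polychoric_matrix(matrix: OrdinalItemMatrix, min_pair_n: int = 10,
                      compute_acov: bool = True) -> PolychoricSummary:
    """Polychoric summary of an ordinal item matrix (pairwise-present)."""
    X = matrix.values
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 items")
    thresholds = []
    for j in range(p):
        col = X[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            raise ValueError(f"item {matrix.items[j]} fully missing")
        counts = np.bincount(obs, minlength=matrix.n_categories[j])
        try:
            thresholds.append(estimate_thresholds(counts))
        except ValueError as e:
            raise ValueError(f"item {matrix.items[j]}: {e}") from e

    R = np.eye(p)
    npair = np.full((p, p), n, dtype=int)
    tables = {}
    for j in range(p):
        for k in range(j + 1, p):
            t, m = _pair_table(X[:, j], X[:, k], matrix.n_categories[j],
                               matrix.n_categories[k])
            if m < min_pair_n:
                raise ValueError(
                    f"pair ({matrix.items[j]}, {matrix.items[k]}): only {m} "
                    f"complete cases")
            rho, _ = estimate_polychoric_pair(t, thresholds[j], thresholds[k])
            R[j, k] = R[k, j] = rho
            npair[j, k] = npair[k, j] = m
            tables[(j, k)] = t

    R_pd = _repair_pd(R)
    if compute_acov:
        acov = _acov_two_stage(X, matrix.n_categories, thresholds, R, tables)
    else:
        acov = np.full((0, 0), np.nan)
    return PolychoricSummary(
        items=list(matrix.items), n_categories=list(matrix.n_categories),
        thresholds=thresholds, R=R, R_pd=R_pd, n_pairwise=npair, n=n,
        acov_full=acov,
        acov_diag=np.diag(acov).copy() if compute_acov else np.empty(0),
    )


def _repair_pd(R, eps=1e-6):
    w = np.linalg.eigvalsh(R)
    if w.min() >= eps:
        return R.copy()
    warnings.warn(f"polychoric matrix not positive definite (min eig "
                  f"{w.min():.3g}); ridge-repaired")
    shift = eps - w.min()
    R2 = R + shift * np.eye(R.shape[0])
    d = 1.0 / np.sqrt(np.diag(R2))
    return R2 * np.outer(d, d)


def _acov_two_stage(X, n_categories, thresholds, R, tables):
    """acov of the stacked (thresholds, correlations) two-stage estimator."""
    n, p = X.shape
    tau_offsets = np.cumsum([0] + [len(t) for t in thresholds])
    q_t = int(tau_offsets[-1])
    pairs = [(j, k) for j in range(p) for k in range(j + 1, p)]
    q = q_t + len(pairs)

    G = np.zeros((n, q))
    A = np.zeros((q, q))

    # threshold blocks
    for j in range(p):
        col = X[:, j]
        obs = col != MISSING
        tj = thresholds[j]
        for k, tau in enumerate(tj):
            idx = tau_offsets[j] + k
            G[obs, idx] = (col[obs] <= k).astype(float) - ndtr(tau)
            A[idx, idx] = (obs.sum() / n) * norm.pdf(tau)

    # correlation rows
    h = 1e-5
    for r, (j, k) in enumerate(pairs):
        idx = q_t + r
        rho = R[j, k]
        tj, tk = thresholds[j], thresholds[k]
        pr = cell_probs(tj, tk, rho)
        dlog = cell_probs_drho(tj, tk, rho) / pr
        tab = tables[(j, k)]
        ok = (X[:, j] != MISSING) & (X[:, k] != MISSING)
        G[ok, idx] = dlog[X[ok, j], X[ok, k]]
        # A[rho, rho]: observed information of the pair likelihood / n
        nllf = _pair_nll(tab, tj, tk)
        A[idx, idx] = (nllf(rho + h) - 2.0 * nllf(rho) + nllf(rho - h)) / h**2 / n
        # A[rho, tau]: numeric derivative of the (negative) mean score wrt tau

        def mean_score(tja, tka):
            prr = cell_probs(tja, tka, rho)
            return float(np.sum(tab * cell_probs_drho(tja, tka, rho) / prr)) / n

        for item, toff, tvec in ((j, tau_offsets[j], tj), (k, tau_offsets[k], tk)):
            for m in range(len(tvec)):
                tp = tvec.copy(); tp[m] += h
                tm = tvec.copy(); tm[m] -= h
                if item == j:
                    d = (mean_score(tp, tk) - mean_score(tm, tk)) / (2 * h)
                else:
                    d = (mean_score(tj, tp) - mean_score(tj, tm)) / (2 * h)
                A[idx, toff + m] = -d

    B = (G.T @ G) / n
    Ainv = np.linalg.solve(A, np.eye(q))
    return Ainv @ B @ Ainv.T / n
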