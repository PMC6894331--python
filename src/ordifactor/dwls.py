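"""Diagonally weighted least squares estimation for ordinal CFA, with
mean-and-variance adjusted test statistics.

The discrepancy ``F = (s - sigma(theta))' W^-1 (s - sigma(theta))`` is
minimised with ``W = diag(acov)`` of the stacked sample thresholds and
polychoric correlations. Because the acov here already carries the 1/n
factor, the minimised F is itself on the chi-square scale. The raw F is
miscalibrated under DWLS, so a scaled-and-shifted second-order
correction is applied: with U the residual weight projector and Gamma
the full asymptotic covariance, F is linearly transformed to match the
mean and variance of a chi-square with the model's integer degrees of
freedom. The same construction applied to U-differences yields the
adjusted chi-square difference test for nested models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.stats import chi2, ncx2

from .model import ModelSpec, implied_jacobian, implied_stat_vector
from .polychoric import PolychoricSummary

__all__ = ["FitResult", "DiffTestResult", "fit_dwls", "fit_indices",
           "residual_matrix", "difftest"]


@dataclass
class FitResult:
    spec: ModelSpec
    theta: np.ndarray
    se: np.ndarray
    F_min: float
    chi2: float | None
    df: int
    scale_shift: tuple[float, float]
    chi2_baseline: float | None
    df_baseline: int
    cfi: float | None
    rmsea: float | None
    rmsea_ci: tuple[float, float] | None
    residuals: list[np.ndarray]
    converged: bool
    n_effective: int
    s: np.ndarray = field(repr=False, default=None)
    W: np.ndarray = field(repr=False, default=None)
    U: np.ndarray = field(repr=False, default=None)
    Gamma: np.ndarray = field(repr=False, default=None)
    implied_R: list[np.ndarray] = field(repr=False, default=None)

    @property
    def param_table(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.spec.param_names,
                             "estimate": self.theta, "se": self.se})

    def estimates(self, g: int = 0) -> dict:
        """Filled model matrices for group ``g``."""
        out = {}
        for (gi, name), slot in self.spec.slots.items():
            if gi == g:
                out[name] = slot.fill(self.theta)
        return out

    def to_json_dict(self) -> dict:
        """Exportable summary: fit statistics plus the parameter table."""
        return {
            "converged": bool(self.converged),
            "chi2": self.chi2, "df": int(self.df),
            "chi2_baseline": self.chi2_baseline,
            "df_baseline": int(self.df_baseline),
            "cfi": self.cfi, "rmsea": self.rmsea,
            "rmsea_ci": list(self.rmsea_ci) if self.rmsea_ci else None,
            "scale_shift": list(self.scale_shift),
            "n": int(self.n_effective),
            "parameters": self.param_table.to_dict(orient="records"),
        }


@dataclass
class DiffTestResult:
    chi2_diff: float
    df_diff: int
    p_value: float
    raw_diff: float


def _tau_rho_masks(summaries):
    """Boolean masks of threshold vs correlation coordinates in the
    stacked moment vector."""
    tau_mask = []
    for sm in summaries:
        q_t = sm.n_thresh
        q_r = len(sm.pairs)
        tau_mask.extend([True] * q_t + [False] * q_r)
    tau_mask = np.array(tau_mask)
    return tau_mask, ~tau_mask


def _set_tau_starts(spec: ModelSpec, summaries, start):
    for g, sm in enumerate(summaries):
        slot = spec.slot(g, "tau")
        sample = np.concatenate(sm.thresholds)
        mask = slot.idx >= 0
        start[slot.idx[mask]] = sample[mask]
    return start


def fit_dwls(summaries, spec: ModelSpec, compute_stats: bool = True,
             max_nfev: int | None = None,
             start_override: np.ndarray | None = None) -> FitResult:
    """Fit ``spec`` to one summary per group by diagonally weighted least
    squares; returns estimates, sandwich standard errors, the adjusted
    test statistic and global fit indices."""
    if isinstance(summaries, PolychoricSummary):
        summaries = [summaries]
    if len(summaries) != spec.n_groups:
        raise ValueError("one PolychoricSummary per group required")
    s = np.concatenate([sm.stat_vector() for sm in summaries])
    w = np.concatenate([sm.acov_diag for sm in summaries])
    if np.any(w <= 0):
        raise ValueError("non-positive weight in acov diagonal")
    sw = np.sqrt(w)
    n_total = sum(sm.n for sm in summaries)

    if start_override is not None:
        start = start_override.copy()
    else:
        start = _set_tau_starts(spec, summaries, spec.start.copy())
    start = np.clip(start, spec.lower + 1e-10, spec.upper - 1e-10)

    def resid(th):
        return (implied_stat_vector(spec, th) - s) / sw

    def jac(th):
        return implied_jacobian(spec, th) / sw[:, None]

    # large multi-group problems: skip the per-variable jacobian scaling
    # and relax termination slightly — the exact trust-region solver
    # factorizes the full Jacobian every iteration
    big = len(s) * spec.n_free > 150_000
    res = least_squares(resid, start, jac=jac,
                        bounds=(spec.lower, spec.upper),
                        method="trf", tr_solver="exact",
                        x_scale=1.0 if big else "jac",
                        xtol=1e-9 if big else 1e-10,
                        ftol=1e-9 if big else 1e-10,
                        gtol=1e-8, max_nfev=max_nfev)
    theta = res.x
    F = float(2.0 * res.cost)
    J_opt = res.jac
    converged = res.status > 0
    df = len(s) - spec.n_free
    if df < 0:
        raise ValueError(f"model not identified: df = {df} < 0")

    # Heywood screen: residual variances at their lower bound
    for (g, name), slot in spec.slots.items():
        if name in ("theta", "psi_sub", "disturb", "psi_zeta", "phi"):
            vals = slot.fill(theta)
            free = slot.idx >= 0
            if np.any(free & (vals <= spec.lower[np.maximum(slot.idx, 0)] + 1e-8)):
                warnings.warn(f"variance parameter at lower bound in slot "
                              f"{name!r} (group {g}); possible Heywood case")

    resids, implied_R = _residual_matrices(spec, theta, summaries)

    if not (compute_stats and converged):
        return FitResult(spec, theta, np.full_like(theta, np.nan), F, None, df,
                         (np.nan, np.nan), None, _baseline_df(summaries), None,
                         None, None, resids, converged, n_total, s=s, W=w,
                         implied_R=implied_R)

    J = J_opt                         # d resid / d theta = Delta / sqrt(w)
    if not isinstance(J, np.ndarray):
        J = J.toarray()
    Gammas = [sm.acov_full for sm in summaries]   # block-diagonal Gamma
    H = J.T @ J                       # Delta' W^-1 Delta
    Hinv = np.linalg.pinv(H)
    # U = W^-1 - W^-1 Delta Hinv Delta' W^-1 ; Delta/w = J/sqrt(w)
    Jw = J / sw[:, None]
    U = np.diag(1.0 / w) - Jw @ Hinv @ Jw.T
    T_adj, scale, shift = _adjust_statistic(F, df, U, Gammas)

    # sandwich covariance of the estimates (blockwise middle product)
    offs = _block_offsets(Gammas)
    mid = np.zeros((spec.n_free, spec.n_free))
    for (lo, hi), G in zip(offs, Gammas):
        mid += Jw[lo:hi].T @ G @ Jw[lo:hi]
    cov = Hinv @ mid @ Hinv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    # independence baseline: free thresholds, zero correlations
    tau_mask, rho_mask = _tau_rho_masks(summaries)
    F_B = float(np.sum(s[rho_mask] ** 2 / w[rho_mask]))
    df_B = int(rho_mask.sum())
    u_B = np.where(rho_mask, 1.0 / w, 0.0)
    T_B, _, _ = _adjust_diag_statistic(F_B, df_B, u_B, Gammas)

    cfi, rmsea, ci = fit_indices(T_adj, df, T_B, df_B, n_total,
                                 n_groups=spec.n_groups)
    return FitResult(spec, theta, se, F, T_adj, df, (scale, shift), T_B, df_B,
                     cfi, rmsea, ci, resids, converged, n_total, s=s, W=w,
                     U=U, Gamma=Gammas, implied_R=implied_R)


def _baseline_df(summaries):
    return sum(len(sm.pairs) for sm in summaries)


def _block_offsets(Gammas):
    sizes = [G.shape[0] for G in Gammas]
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [(int(edges[i]), int(edges[i + 1])) for i in range(len(sizes))]


def _trace_products(U, Gammas):
    """tr(U Gamma) and tr((U Gamma)^2) with block-diagonal Gamma."""
    offs = _block_offsets(Gammas)
    a = sum(float(np.sum(U[lo:hi, lo:hi] * G))
            for (lo, hi), G in zip(offs, Gammas))
    M = np.empty_like(U)
    for (lo, hi), G in zip(offs, Gammas):
        M[:, lo:hi] = U[:, lo:hi] @ G
    b = float(np.sum(M * M.T))
    return a, b


def _adjust_statistic(F, df, U, Gammas):
    """Scaled-and-shifted statistic matching mean df and variance 2 df."""
    if df == 0:
        return 0.0, 1.0, 0.0
    a, b = _trace_products(U, Gammas)
    if b <= 0:
        return max(F, 0.0), 1.0, 0.0
    scale = np.sqrt(df / b)
    shift = df - scale * a
    return max(scale * F + shift, 0.0), scale, shift


def _adjust_diag_statistic(F, df, u, Gammas):
    """As _adjust_statistic for a diagonal U (the independence baseline)."""
    if df == 0:
        return 0.0, 1.0, 0.0
    offs = _block_offsets(Gammas)
    a = b = 0.0
    for (lo, hi), G in zip(offs, Gammas):
        ug = u[lo:hi]
        a += float(ug @ np.diag(G))
        b += float(ug @ (G * G) @ ug)
    if b <= 0:
        return max(F, 0.0), 1.0, 0.0
    scale = np.sqrt(df / b)
    shift = df - scale * a
    return max(scale * F + shift, 0.0), scale, shift


def fit_indices(T, df, T_B, df_B, n, n_groups: int = 1):
    """CFI, RMSEA and the 90% RMSEA interval from (adjusted) statistics."""
    if df == 0:
        return None, None, None
    num = max(T - df, 0.0)
    den = max(T_B - df_B, T - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    G = n_groups
    rmsea = np.sqrt(G * num / (df * n))
    ci = (_rmsea_bound(T, df, n, G, 0.95), _rmsea_bound(T, df, n, G, 0.05))
    return cfi, rmsea, ci


def _rmsea_bound(T, df, n, G, prob):
    """Noncentrality lambda with ncx2.cdf(T, df, lambda) = prob, mapped to
    the RMSEA scale."""
    if ncx2.cdf(T, df, 0.0) < prob:  # even lambda = 0 puts too little mass below T
        return 0.0
    hi = max(T, 1.0)
    while ncx2.cdf(T, df, hi) > prob:
        hi *= 2.0
        if hi > 1e8:
            break
    lam = brentq(lambda l: ncx2.cdf(T, df, l) - prob, 0.0, hi, xtol=1e-8)
    return float(np.sqrt(G * lam / (df * n)))


def _residual_matrices(spec, theta, summaries):
    resids, implied = [], []
    ncat = np.asarray(spec.n_categories)
    q_t = int(np.sum(ncat - 1))
    sigma = implied_stat_vector(spec, theta)
    pos = 0
    for sm in summaries:
        p = sm.p
        block = sigma[pos:pos + q_t + len(sm.pairs)]
        rho_imp = block[q_t:]
        P = np.eye(p)
        iu = np.triu_indices(p, 1)
        P[iu] = rho_imp
        P[(iu[1], iu[0])] = rho_imp
        resids.append(sm.R - P)
        implied.append(P)
        pos += q_t + len(sm.pairs)
    return resids, implied


def residual_matrix(fit: FitResult, group: int = 0, top: int = 10):
    """Observed-minus-implied correlations with a ranked report of the
    largest absolute discrepancies (local-fit assessment)."""
    R = fit.residuals[group]
    items = fit.spec.items
    iu = np.triu_indices(R.shape[0], 1)
    order = np.argsort(-np.abs(R[iu]))[:top]
    report = pd.DataFrame({
        "item_1": [items[iu[0][i]] for i in order],
        "item_2": [items[iu[1][i]] for i in order],
        "residual": R[iu][order],
    })
    return R, report


def difftest(nested_fit: FitResult, parent_fit: FitResult) -> DiffTestResult:
    """Adjusted chi-square difference test between nested DWLS fits on the
    same data (nested = more constrained)."""
    if nested_fit.s is None or parent_fit.s is None:
        raise ValueError("fits lack stored sample statistics")
    if nested_fit.s.shape != parent_fit.s.shape or not np.allclose(
            nested_fit.s, parent_fit.s):
        raise ValueError("difftest requires fits on the same data")
    df_d = nested_fit.df - parent_fit.df
    if df_d <= 0:
        raise ValueError("models are not nested (df difference must be > 0)")
    if nested_fit.U is None or parent_fit.U is None:
        raise ValueError("difftest requires fits with computed statistics")
    T_raw = nested_fit.F_min - parent_fit.F_min
    if T_raw < -1e-6:
        warnings.warn("nested discrepancy below parent discrepancy; check "
                      "nesting / convergence")
    D = nested_fit.U - parent_fit.U
    a, b = _trace_products(D, nested_fit.Gamma)
    if b <= 0:
        T_adj = max(T_raw, 0.0)
    else:
        scale = np.sqrt(df_d / b)
        T_adj = scale * max(T_raw, 0.0) + (df_d - scale * a)
    if T_adj < 0:
        warnings.warn("negative adjusted difference statistic floored at 0")
        T_adj = 0.0
    p = float(chi2.sf(T_adj, df_d))
    return DiffTestResult(chi2_diff=T_adj, df_diff=df_d, p_value=p,
                          raw_diff=max(T_raw, 0.0))
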