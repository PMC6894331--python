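"""Bifactor-derived reliability and dimensionality indices.

All indices are computed from the completely standardized bifactor
solution on the latent-response scale (each item satisfies
lambda_g^2 + lambda_s^2 + theta = 1):

* omega — model-based reliability of the unit-weighted total score from
  all common factors;
* omega_H — the share attributable to the general factor alone (> 0.80
  marks a dominant general factor);
* omega_HS — per-subdomain reliability after removing general-factor
  variance;
* ECV — the general factor's share of all common variance;
* H — construct replicability of the general factor, the proportion of
  its variance explainable by its own indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dwls import FitResult

__all__ = ["BifactorIndices", "bifactor_indices", "variance_decomposition",
           "standardized_bifactor"]


@dataclass
class BifactorIndices:
    omega_total: float
    omega_h: float
    omega_hs: np.ndarray
    ecv: float
    H: float
    H_sub: np.ndarray
    general_share: float
    multidim_share: float
    error_share: float

    def paragraph(self) -> str:
        hs = ", ".join(f"omega_HS{f + 1} = {v:.2f}"
                       for f, v in enumerate(self.omega_hs))
        return (
            f"Reliability: omega = {self.omega_total:.2f}, omega_H = "
            f"{self.omega_h:.2f}; {self.general_share:.2f} of the reliable "
            f"total-score variance is attributable to the general factor, "
            f"{self.multidim_share * 100:.0f}% to the subdomain factors and "
            f"{self.error_share * 100:.0f}% to random error. Subscale "
            f"coefficients: {hs}. ECV = {self.ecv:.2f}; H = {self.H:.2f}."
        )


def bifactor_indices(lambda_general, lambda_sub, theta_std,
                     tol: float = 1e-6) -> BifactorIndices:
    """Indices from a completely standardized bifactor solution.

    ``lambda_general``: (p,) general-factor loadings; ``lambda_sub``:
    (p, m) subdomain loadings (zero off-assignment); ``theta_std``: (p,)
    standardized residual variances.
    """
    lg = np.asarray(lambda_general, dtype=float)
    Ls = np.atleast_2d(np.asarray(lambda_sub, dtype=float))
    if Ls.shape[0] != lg.shape[0]:
        Ls = Ls.T
    th = np.asarray(theta_std, dtype=float)
    total = lg**2 + (Ls**2).sum(axis=1) + th
    if np.any(np.abs(total - 1.0) > tol):
        worst = float(np.abs(total - 1.0).max())
        raise ValueError(f"solution not completely standardized "
                         f"(max |1 - var| = {worst:.2e})")

    m = Ls.shape[1]
    sum_g = lg.sum()
    sum_f = Ls.sum(axis=0)                     # per-subdomain loading sums
    denom = sum_g**2 + (sum_f**2).sum() + th.sum()
    omega = (sum_g**2 + (sum_f**2).sum()) / denom
    omega_h = sum_g**2 / denom

    omega_hs = np.zeros(m)
    for f in range(m):
        members = Ls[:, f] != 0
        if not members.any():
            continue
        sg = lg[members].sum()
        sf = Ls[members, f].sum()
        omega_hs[f] = sf**2 / (sg**2 + sf**2 + th[members].sum())

    ecv_num = (lg**2).sum()
    ecv = ecv_num / (ecv_num + (Ls**2).sum())

    def h_index(lam):
        r = lam**2 / np.maximum(1.0 - lam**2, 1e-12)
        return float(r.sum() / (1.0 + r.sum()))

    H = h_index(lg)
    H_sub = np.array([h_index(Ls[Ls[:, f] != 0, f]) for f in range(m)]) \
        if m else np.empty(0)

    gs, ms, es = variance_decomposition(omega, omega_h)
    return BifactorIndices(omega_total=float(omega), omega_h=float(omega_h),
                           omega_hs=omega_hs, ecv=float(ecv), H=H,
                           H_sub=H_sub, general_share=gs, multidim_share=ms,
                           error_share=es)


def variance_decomposition(omega_total: float, omega_h: float):
    """Split unit-weighted total-score variance into the general-factor
    share (omega_H / omega), the multidimensionality share
    (omega - omega_H) and random error (1 - omega)."""
    if not 0 <= omega_h <= omega_total <= 1:
        raise ValueError("need 0 <= omega_H <= omega <= 1")
    if omega_total == 0:
        return float("nan"), 0.0, 1.0
    return (omega_h / omega_total, omega_total - omega_h, 1.0 - omega_total)


def standardized_bifactor(fit: FitResult, group: int = 0):
    """Completely standardized (lambda_general, lambda_sub, theta) from a
    fitted bifactor model (theta parameterization, any identification)."""
    est = fit.estimates(group)
    L = est["lambda"]
    psi = est["psi"]
    theta = est["theta"]
    # scale loadings by factor sd, then standardize by item sd
    Lsc = L * np.sqrt(np.diag(psi))
    sd = np.sqrt((Lsc**2).sum(axis=1) + theta)
    L_std = Lsc / sd[:, None]
    th_std = theta / sd**2
    return L_std[:, 0], L_std[:, 1:], th_std
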