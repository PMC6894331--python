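"""Exploratory factor analysis on the polychoric matrix.

Extraction reuses the DWLS engine: an m-factor EFA is fitted as a
rotation-indeterminate CFA with an echelon loading pattern (zeros above
the diagonal of the first m rows), identity factor covariance and unit
residual variances. Oblique parsimax rotation — the Crawford-Ferguson
family at kappa = (m - 1)/(p + m - 2) — is carried out by gradient
projection with random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dwls import FitResult, fit_dwls
from .model import FIXED, ModelSpec, ParamAllocator, Slot
from .polychoric import PolychoricSummary
from .structures import _tau_slot

__all__ = ["EFASolution", "ItemAssignment", "extract", "parsimax_rotate",
           "assign_items", "cf_criterion"]


@dataclass
class EFASolution:
    m: int
    eigenvalues: np.ndarray
    loadings_unrotated: np.ndarray   # standardized, item x m
    loadings_rotated: np.ndarray | None
    factor_corr: np.ndarray | None
    fit: FitResult

    def rotated_table(self, items) -> pd.DataFrame:
        L = self.loadings_rotated if self.loadings_rotated is not None \
            else self.loadings_unrotated
        df = pd.DataFrame(L, index=items,
                          columns=[f"factor{f + 1}" for f in range(self.m)])
        df["assigned"] = np.argmax(np.abs(L), axis=1) + 1
        return df


@dataclass
class ItemAssignment:
    assignment: np.ndarray           # item -> factor index
    non_congeneric: np.ndarray       # bool flags: salient on >= 2 factors
    near_tie: np.ndarray             # bool flags: top two |loadings| close
    below_cutoff: np.ndarray         # bool flags: max |loading| < cutoff


def _echelon_spec(items, n_categories, m) -> ModelSpec:
    p = len(items)
    alloc = ParamAllocator()
    spec = ModelSpec(kind="cfa", items=list(items),
                     n_categories=list(n_categories),
                     factors=[f"f{f + 1}" for f in range(m)], groups=["all"],
                     meta={"structure": "efa"})
    lam_idx = np.full((p, m), FIXED, dtype=int)
    for j in range(p):
        for f in range(min(j + 1, m)):
            lam_idx[j, f] = alloc.new(f"lambda[{items[j]},f{f + 1}]", 0.4, lower=-8.0, upper=8.0)
    spec.slots[(0, "lambda")] = Slot(lam_idx, np.zeros((p, m)))
    spec.slots[(0, "psi")] = Slot.fixed(np.eye(m))
    spec.slots[(0, "theta")] = Slot.fixed(np.ones(p))
    spec.slots[(0, "alpha")] = Slot.fixed(np.zeros(m))
    spec.slots[(0, "tau")] = _tau_slot(alloc, items, n_categories)
    return spec.finish(alloc)


def extract(summary: PolychoricSummary, m: int) -> EFASolution:
    """Unrotated m-factor DWLS solution plus the eigenvalues of the
    polychoric matrix."""
    p = summary.p
    if not 1 <= m < p:
        raise ValueError("need 1 <= m < number of items")
    df_model = p * (p - 1) // 2 - (p * m - m * (m - 1) // 2)
    if df_model < 0:
        raise ValueError(f"{m} factors are not identified for {p} items "
                         f"(df = {df_model})")
    eig = np.sort(np.linalg.eigvalsh(summary.R))[::-1]
    spec = _echelon_spec(summary.items, summary.n_categories, m)

    # principal-axis start rotated to echelon form
    w, V = np.linalg.eigh(summary.R_pd)
    order = np.argsort(w)[::-1][:m]
    L0 = V[:, order] * np.sqrt(np.maximum(w[order], 0.01))
    Q, _ = np.linalg.qr(L0[:m, :].T)
    L0 = L0 @ Q
    h2 = np.minimum((L0**2).sum(1), 0.95)
    L0_raw = L0 / np.sqrt(1.0 - h2)[:, None]
    lam_slot = spec.slot(0, "lambda")
    mask = lam_slot.idx >= 0
    spec.start[lam_slot.idx[mask]] = L0_raw[mask]

    fit = fit_dwls(summary, spec)
    L_raw = fit.estimates(0)["lambda"]
    sd = np.sqrt((L_raw**2).sum(1) + 1.0)
    L_std = L_raw / sd[:, None]
    return EFASolution(m=m, eigenvalues=eig, loadings_unrotated=L_std,
                       loadings_rotated=None, factor_corr=None, fit=fit)


def cf_criterion(L, kappa):
    """Crawford-Ferguson criterion value and gradient at loadings L."""
    p, m = L.shape
    L2 = L**2
    N = np.ones((m, m)) - np.eye(m)
    M = np.ones((p, p)) - np.eye(p)
    f = ((1 - kappa) / 4 * np.sum(L2 * (L2 @ N))
         + kappa / 4 * np.sum(L2 * (M @ L2)))
    G = (1 - kappa) * L * (L2 @ N) + kappa * L * (M @ L2)
    return f, G


def _gpa_oblique(A, kappa, T0, max_iter=500, tol=1e-7):
    """Gradient-projection oblique rotation (Bernaards & Jennrich)."""
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = cf_criterion(L, kappa)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            X = X / np.sqrt((X**2).sum(axis=0))
            Ti = np.linalg.inv(X)
            Lt = A @ Ti.T
            ft, Gq = cf_criterion(Lt, kappa)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        else:
            break
        T, f, L = X, ft, Lt
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi, f


def parsimax_rotate(loadings, n_starts: int = 10, seed: int = 0):
    """Oblique parsimax rotation of a standardized loading matrix.

    Runs gradient projection from the identity plus ``n_starts`` random
    orthonormal starts and keeps the best criterion value. Each factor is
    oriented so its largest-|loading| item is positive; returns
    ``(rotated_loadings, factor_correlations, criterion_value)``.
    """
    A = np.asarray(loadings, dtype=float)
    p, m = A.shape
    if m == 1:
        return A.copy(), np.ones((1, 1)), 0.0
    kappa = (m - 1) / (p + m - 2)
    rng = np.random.default_rng(seed)
    starts = [np.eye(m)]
    for _ in range(n_starts):
        Q, _ = np.linalg.qr(rng.standard_normal((m, m)))
        starts.append(Q)
    best = None
    for T0 in starts:
        L, Phi, f = _gpa_oblique(A, kappa, T0)
        if best is None or f < best[2] - 1e-12:
            best = (L, Phi, f)
    L, Phi, f = best
    # sign convention
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(m)])
    signs[signs == 0] = 1.0
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    return L, Phi, f


def assign_items(rotated, cutoff: float = 0.20, salient: float = 0.40,
                 tie_margin: float = 0.05) -> ItemAssignment:
    """Map each item to its highest-|loading| factor; flag items salient
    on two factors (non-congeneric), near-ties, and items whose best
    loading falls below the cutoff (kept, but flagged). Ties break toward
    the lower factor index."""
    L = np.abs(np.asarray(rotated, dtype=float))
    assignment = np.argmax(L, axis=1)  # argmax breaks ties toward lower index
    non_cong = (L > salient).sum(axis=1) >= 2
    sorted_L = np.sort(L, axis=1)
    near_tie = (sorted_L[:, -1] - sorted_L[:, -2]) < tie_margin if L.shape[1] > 1 \
        else np.zeros(L.shape[0], bool)
    below = L.max(axis=1) < cutoff
    return ItemAssignment(assignment=assignment, non_congeneric=non_cong,
                          near_tie=near_tie, below_cutoff=below)
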