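"""Bivariate standard-normal primitives.

The polychoric likelihood needs rectangle probabilities
P(a0 < X <= a1, b0 < Y <= b1) under a standard bivariate normal with
correlation rho, plus their derivative with respect to rho (Plackett's
identity: the bivariate density summed over rectangle corners with
alternating signs). The CDF is evaluated through Owen's T function,
which is vectorised and accurate to ~1e-14 — well inside the 1e-10
tolerance the fitting code assumes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import owens_t, ndtr

__all__ = ["bvn_cdf", "bvn_pdf", "cell_probs", "cell_probs_drho"]

_TINY = 1e-15


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Accepts array-like ``h``/``k`` (broadcast together); ``rho`` is scalar.
    Infinite bounds are handled (reduce to univariate CDF / 0).
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(rho)
    if rho >= 1.0 - 1e-12:
        return np.where(np.isneginf(np.minimum(h, k)), 0.0, ndtr(np.minimum(h, k)))
    if rho <= -1.0 + 1e-12:
        return np.maximum(ndtr(h) + ndtr(k) - 1.0, 0.0)

    out = np.empty(h.shape, dtype=float)
    # infinite-bound cases reduce exactly
    neg = np.isneginf(h) | np.isneginf(k)
    hi_h = np.isposinf(h) & ~neg
    hi_k = np.isposinf(k) & ~neg
    both_inf = hi_h & hi_k
    fin = ~(neg | hi_h | hi_k)
    out[neg] = 0.0
    out[both_inf] = 1.0
    out[hi_h & ~both_inf] = ndtr(k[hi_h & ~both_inf])
    out[hi_k & ~both_inf] = ndtr(h[hi_k & ~both_inf])

    if np.any(fin):
        hf = h[fin].copy()
        kf = k[fin].copy()
        # Owen's formula is singular at an exactly-zero bound; nudge off zero.
        hf[hf == 0.0] = _TINY
        kf[kf == 0.0] = _TINY
        denom = np.sqrt(1.0 - rho * rho)
        ah = (kf - rho * hf) / (hf * denom)
        ak = (hf - rho * kf) / (kf * denom)
        beta = np.where(hf * kf < 0.0, 0.5, 0.0)
        val = (
            0.5 * (ndtr(hf) + ndtr(kf))
            - owens_t(hf, ah)
            - owens_t(kf, ak)
            - beta
        )
        out[fin] = np.clip(val, 0.0, 1.0)
    return out


def bvn_pdf(h, k, rho):
    """Standard bivariate normal density; zero at infinite arguments."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(rho)
    omr2 = max(1.0 - rho * rho, 1e-12)
    finite = np.isfinite(h) & np.isfinite(k)
    out = np.zeros(h.shape, dtype=float)
    hf, kf = h[finite], k[finite]
    z = (hf * hf - 2.0 * rho * hf * kf + kf * kf) / omr2
    out[finite] = np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(omr2))
    return out


def _extend(thresholds):
    t = np.asarray(thresholds, dtype=float)
    return np.concatenate(([-np.inf], t, [np.inf]))


def cell_probs(t1, t2, rho, floor=1e-12):
    """Cell probabilities of the two-way table implied by thresholds and rho.

    ``t1``/``t2`` are the interior thresholds of the two ordinal margins;
    returns a (K1, K2) matrix summing to 1 (up to flooring at ``floor``).
    """
    a = _extend(t1)
    b = _extend(t2)
    big = bvn_cdf(a[:, None], b[None, :], rho)
    p = big[1:, 1:] - big[:-1, 1:] - big[1:, :-1] + big[:-1, :-1]
    return np.maximum(p, floor)


def cell_probs_drho(t1, t2, rho):
    """d/d rho of each cell probability (Plackett's identity)."""
    a = _extend(t1)
    b = _extend(t2)
    dens = bvn_pdf(a[:, None], b[None, :], rho)
    return dens[1:, 1:] - dens[:-1, 1:] - dens[1:, :-1] + dens[:-1, :-1]
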