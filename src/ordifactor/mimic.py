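"""Concurrent convergent validity via a MIMIC model.

The bifactor measurement model is extended with observed causes: the
criterion (self-rated health) and adjustment covariates (sex, age band)
predict the general factor. All observed variables, including the
causes, are treated as ordinal with latent-normal responses, so the
model is fitted to the polychoric correlation matrix of items plus
causes by the same DWLS machinery. The reported coefficient is the
standardized effect of the criterion on the general factor, with a
seeded percentile-bootstrap confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dwls import FitResult, fit_dwls
from .item_prep import MISSING, OrdinalItemMatrix
from .model import FIXED, ModelSpec, ParamAllocator, Slot
from .polychoric import polychoric_matrix

__all__ = ["MimicResult", "build_mimic_spec", "fit_mimic"]


@dataclass
class MimicResult:
    beta_std: float                    # standardized criterion effect
    beta_raw: float
    covariate_betas_std: dict[str, float]
    ci: tuple[float, float] | None     # percentile bootstrap 95% CI
    bootstrap_draws: np.ndarray | None
    n_bootstrap_ok: int
    fit: FitResult


def build_mimic_spec(items, n_categories, assignment, xvars,
                     x_categories) -> ModelSpec:
    """Bifactor measurement model plus structural regressions of the
    general factor on the observed causes; causes are saturated among
    themselves. Identification: general referent loading fixed to 1,
    subdomain factor variances fixed to 1, residual variances fixed to 1.
    """
    p = len(items)
    q = len(xvars)
    if assignment is None:
        m = 0
        assignment = np.full(p, -1)
    else:
        assignment = np.asarray(assignment)
        m = int(assignment.max()) + 1
    alloc = ParamAllocator()
    allvars = list(items) + list(xvars)
    allcats = list(n_categories) + list(x_categories)
    spec = ModelSpec(kind="mimic", items=allvars, n_categories=allcats,
                     factors=["general"] + [f"sub{f + 1}" for f in range(m)],
                     groups=["all"], n_xvars=q,
                     meta={"structure": "mimic", "n_indicators": p})

    lam_idx = np.full((p, m + 1), FIXED, dtype=int)
    lam_fix = np.zeros((p, m + 1))
    lam_fix[0, 0] = 1.0
    for j in range(p):
        if j > 0:
            lam_idx[j, 0] = alloc.new(f"lambda[{items[j]},general]", 0.7,
                                      lower=-8.0, upper=8.0)
        f = assignment[j]
        if f >= 0:
            lam_idx[j, f + 1] = alloc.new(f"lambda[{items[j]},sub{f + 1}]",
                                          0.3, lower=-8.0, upper=8.0)
    spec.slots[(0, "lambda")] = Slot(lam_idx, lam_fix)
    spec.slots[(0, "psi_sub")] = Slot.fixed(np.ones(m))
    spec.slots[(0, "psi_zeta")] = Slot(
        np.array([alloc.new("psi[zeta]", 0.5, lower=1e-6)]), np.zeros(1))
    beta_idx = np.array([alloc.new(f"beta[{x}]", 0.1) for x in xvars])
    spec.slots[(0, "beta")] = Slot(beta_idx, np.zeros(q))
    phix_idx = np.full((q, q), FIXED, dtype=int)
    phix_fix = np.eye(q)
    for a in range(q):
        for b in range(a + 1, q):
            pid = alloc.new(f"phix[{xvars[a]},{xvars[b]}]", 0.0,
                            lower=-0.95, upper=0.95)
            phix_idx[a, b] = phix_idx[b, a] = pid
    spec.slots[(0, "phix")] = Slot(phix_idx, phix_fix)
    spec.slots[(0, "theta")] = Slot.fixed(np.ones(p))

    tau_idx, tau_fix = [], []
    for v, k in zip(allvars, allcats):
        for c in range(k - 1):
            tau_idx.append(alloc.new(f"tau[{v},{c + 1}]", 0.0))
            tau_fix.append(0.0)
    spec.slots[(0, "tau")] = Slot(np.array(tau_idx, dtype=int),
                                  np.array(tau_fix))
    return spec.finish(alloc)


def _extended_matrix(matrix: OrdinalItemMatrix, criterion: str,
                     covariates) -> tuple[OrdinalItemMatrix, list[str], list[int]]:
    cols, names = [], []
    for name in [criterion] + list(covariates):
        if name == "sex":
            v = np.asarray(matrix.sex, dtype=int)
        elif name in matrix.extra:
            v = np.asarray(matrix.extra[name], dtype=int)
        else:
            raise KeyError(f"covariate {name!r} not found in matrix")
        cols.append(v)
        names.append(name)
    X = np.column_stack([matrix.values] + cols)
    xcats = [int(c[c != MISSING].max()) + 1 for c in cols]
    ext = OrdinalItemMatrix(
        values=X, items=matrix.items + names,
        n_categories=matrix.n_categories + xcats,
        group=matrix.group, sex=matrix.sex, age_years=matrix.age_years)
    return ext, names, xcats


def _beta_std(fit: FitResult, q: int):
    est = fit.estimates(0)
    beta = est["beta"]
    phix = est["phix"]
    psi_z = est["psi_zeta"][0]
    var_eta = float(beta @ phix @ beta + psi_z)
    return beta / np.sqrt(var_eta), beta


def fit_mimic(matrix: OrdinalItemMatrix, assignment, criterion: str = "srh",
              covariates=("sex", "ageband"), n_bootstrap: int = 500,
              seed: int = 0, compute_ci: bool = True) -> MimicResult:
    """Fit the MIMIC model and bootstrap the standardized criterion effect.

    ``assignment`` gives the bifactor subdomain of each item (None for a
    plain one-factor measurement model).
    """
    ext, xnames, xcats = _extended_matrix(matrix, criterion, covariates)
    spec = build_mimic_spec(matrix.items, matrix.n_categories, assignment,
                            xnames, xcats)
    summary = polychoric_matrix(ext)
    fit = fit_dwls(summary, spec)
    if not fit.converged:
        raise RuntimeError("MIMIC model did not converge")
    q = len(xnames)
    beta_std, beta_raw = _beta_std(fit, q)
    cov_std = {x: float(b) for x, b in zip(xnames[1:], beta_std[1:])}

    ci, draws, ok = None, None, 0
    if compute_ci and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n_bootstrap):
            rows = rng.integers(0, ext.n, ext.n)
            try:
                # point estimates only: reuse the point fit's DWLS weights
                # instead of re-deriving the asymptotic covariance per draw
                bs = polychoric_matrix(ext.subset(rows), compute_acov=False)
                bs.acov_diag = summary.acov_diag
                bfit = fit_dwls(bs, spec, compute_stats=False,
                                start_override=fit.theta)
                if not bfit.converged:
                    continue
                bstd, _ = _beta_std(bfit, q)
                vals.append(bstd[0])
            except (ValueError, np.linalg.LinAlgError):
                continue
        ok = len(vals)
        if ok < 0.9 * n_bootstrap:
            warnings.warn(f"bootstrap convergence in only {ok}/{n_bootstrap} "
                          "resamples")
        if ok:
            draws = np.array(vals)
            ci = (float(np.percentile(draws, 2.5)),
                  float(np.percentile(draws, 97.5)))
    return MimicResult(beta_std=float(beta_std[0]), beta_raw=float(beta_raw[0]),
                       covariate_betas_std=cov_std, ci=ci,
                       bootstrap_draws=draws, n_bootstrap_ok=ok, fit=fit)
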