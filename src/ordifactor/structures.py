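"""Confirmatory structures: one-factor, second-order and bifactor model
specs built from an item-to-subdomain assignment, plus the
model-comparison protocol (global fit, adjusted difference tests,
local-fit residuals)."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dwls import DiffTestResult, FitResult, difftest
from .model import FIXED, ModelSpec, ParamAllocator, Slot

__all__ = ["build_structure", "compare_structures", "CFI_ACCEPT", "RMSEA_ACCEPT"]

CFI_ACCEPT = 0.90
RMSEA_ACCEPT = 0.06
LARGE_RESIDUAL = 0.10


def _tau_slot(alloc, items, n_categories, g=0, tag=""):
    idx, fix = [], []
    for it, k in zip(items, n_categories):
        for c in range(k - 1):
            idx.append(alloc.new(f"tau[{it},{c + 1}]{tag}", 0.0))
            fix.append(0.0)
    return Slot(idx=np.array(idx, dtype=int), fix=np.array(fix))


def build_structure(kind: str, assignment, items: list[str],
                    n_categories: list[int]) -> ModelSpec:
    """Build a single-group ModelSpec of the given kind.

    ``assignment`` maps each item to a subdomain index (array of length p);
    it is ignored for ``one_factor``. Single-group identification fixes
    factor variances to 1 with all loadings free (the better-conditioned
    choice for bifactor models, where a referent item shared between the
    general and a subdomain factor creates an estimation ridge), residual
    variances to 1 (theta parameterization) and factor means to 0. The
    second-order structure keeps referent loadings (first item per
    first-order factor, first factor for the second-order factor) since
    its factor variances are composite.
    """
    p = len(items)
    assignment = None if kind == "one_factor" else np.asarray(assignment)
    if assignment is not None:
        m = int(assignment.max()) + 1
        sizes = np.bincount(assignment, minlength=m)
        if np.any(sizes < 2):
            bad = int(np.argmin(sizes))
            raise ValueError(f"subdomain {bad} has {sizes[bad]} item(s); "
                             "need at least 2")
        if kind == "second_order" and m == 1:
            warnings.warn("second-order model with one first-order factor "
                          "reduces to the one-factor model")
            kind = "one_factor"

    alloc = ParamAllocator()
    spec = ModelSpec(kind="cfa" if kind != "second_order" else "second_order",
                     items=list(items), n_categories=list(n_categories),
                     factors=[], groups=["all"], meta={"structure": kind})

    if kind == "one_factor":
        spec.factors = ["general"]
        lam_idx = np.full((p, 1), FIXED, dtype=int)
        for j in range(p):
            lam_idx[j, 0] = alloc.new(f"lambda[{items[j]},general]", 0.7, lower=-8.0, upper=8.0)
        spec.slots[(0, "lambda")] = Slot(lam_idx, np.zeros((p, 1)))
        spec.slots[(0, "psi")] = Slot.fixed(np.eye(1))
        spec.slots[(0, "alpha")] = Slot.fixed(np.zeros(1))

    elif kind == "bifactor":
        m = int(assignment.max()) + 1
        spec.factors = ["general"] + [f"sub{f + 1}" for f in range(m)]
        lam_idx = np.full((p, m + 1), FIXED, dtype=int)
        lam_fix = np.zeros((p, m + 1))
        for j in range(p):
            lam_idx[j, 0] = alloc.new(f"lambda[{items[j]},general]", 0.7, lower=-8.0, upper=8.0)
            f = assignment[j]
            lam_idx[j, f + 1] = alloc.new(f"lambda[{items[j]},sub{f + 1}]", 0.4, lower=-8.0, upper=8.0)
        # orthogonal factors with unit variance: Psi = I
        spec.slots[(0, "lambda")] = Slot(lam_idx, lam_fix)
        spec.slots[(0, "psi")] = Slot.fixed(np.eye(m + 1))
        spec.slots[(0, "alpha")] = Slot.fixed(np.zeros(m + 1))

    elif kind == "second_order":
        m = int(assignment.max()) + 1
        spec.factors = [f"f{f + 1}" for f in range(m)]
        lam_idx = np.full((p, m), FIXED, dtype=int)
        lam_fix = np.zeros((p, m))
        for j in range(p):
            f = assignment[j]
            first = int(np.flatnonzero(assignment == f)[0])
            if j == first:
                lam_fix[j, f] = 1.0
            else:
                lam_idx[j, f] = alloc.new(f"lambda[{items[j]},f{f + 1}]", 0.5, lower=-8.0, upper=8.0)
        gam_idx = np.full(m, FIXED, dtype=int)
        gam_fix = np.zeros(m)
        gam_fix[0] = 1.0
        for f in range(1, m):
            gam_idx[f] = alloc.new(f"gamma[f{f + 1}]", 0.5)
        phi_idx = np.array([alloc.new("phi[general]", 0.5, lower=1e-6)])
        dis_idx = np.array([alloc.new(f"disturb[f{f + 1}]", 0.5, lower=1e-6)
                            for f in range(m)])
        spec.slots[(0, "lambda")] = Slot(lam_idx, lam_fix)
        spec.slots[(0, "gamma")] = Slot(gam_idx, gam_fix)
        spec.slots[(0, "phi")] = Slot(phi_idx, np.zeros(1))
        spec.slots[(0, "disturb")] = Slot(dis_idx, np.zeros(m))
        spec.slots[(0, "alpha")] = Slot.fixed(np.zeros(m))
    else:
        raise ValueError(f"unknown structure kind {kind!r}")

    spec.slots[(0, "theta")] = Slot.fixed(np.ones(p))
    spec.slots[(0, "tau")] = _tau_slot(alloc, items, n_categories)
    return spec.finish(alloc)


def compare_structures(fits: dict[str, FitResult],
                       parent: str = "bifactor") -> dict:
    """Rank competing structures: global fit per model, adjusted difference
    tests of nested models against ``parent``, and a local-fit residual
    summary. Selection follows: acceptable global fit, higher CFI, lower
    RMSEA, significant difference tests, fewest large residuals."""
    rows, excluded = [], []
    usable = {}
    for name, fit in fits.items():
        if not fit.converged:
            excluded.append(name)
            continue
        usable[name] = fit
        R = fit.residuals[0]
        iu = np.triu_indices(R.shape[0], 1)
        rows.append({
            "model": name, "chi2": fit.chi2, "df": fit.df, "cfi": fit.cfi,
            "rmsea": fit.rmsea,
            "rmsea_lo": fit.rmsea_ci[0] if fit.rmsea_ci else np.nan,
            "rmsea_hi": fit.rmsea_ci[1] if fit.rmsea_ci else np.nan,
            "acceptable": (fit.cfi is not None and fit.cfi >= CFI_ACCEPT
                           and fit.rmsea <= RMSEA_ACCEPT),
            "n_large_residuals": int(np.sum(np.abs(R[iu]) > LARGE_RESIDUAL)),
            "max_abs_residual": float(np.max(np.abs(R[iu]))),
        })
    table = pd.DataFrame(rows)

    tests: dict[str, DiffTestResult] = {}
    if parent in usable:
        for name, fit in usable.items():
            if name != parent and fit.df > usable[parent].df:
                tests[name] = difftest(fit, usable[parent])

    selected = None
    tie = False
    if len(usable) >= 2:
        key = table.set_index("model")
        order = key.sort_values(["cfi", "rmsea", "n_large_residuals"],
                                ascending=[False, True, True])
        best, runner = order.index[0], order.index[1]
        global_tie = (np.isclose(key.loc[best, "cfi"], key.loc[runner, "cfi"],
                                 atol=1e-4)
                      and np.isclose(key.loc[best, "rmsea"],
                                     key.loc[runner, "rmsea"], atol=1e-4))
        if not global_tie:
            selected = best
            if best == parent and tests:
                # parent must beat every nested competitor significantly
                if not all(t.p_value < 0.05 for t in tests.values()):
                    selected = None
        else:
            # global indices at their ceiling: fall back on the adjusted
            # difference test between the tied pair, then on local fit
            nested = runner if best == parent else best
            if parent in (best, runner) and nested in tests:
                if tests[nested].p_value < 0.05:
                    selected = parent
                elif (key.loc[best, "n_large_residuals"]
                      != key.loc[runner, "n_large_residuals"]):
                    selected = order.index[0]
                else:
                    tie = True
            else:
                tie = True
    elif len(usable) == 1:
        selected = next(iter(usable))

    return {"table": table, "difftests": tests, "selected": selected,
            "tie": tie, "excluded": excluded}
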