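"""Multi-group measurement invariance for ordinal CFA.

Protocol: (1) the selected structure is fitted in each group separately;
(2) a configural multi-group model frees all loadings and thresholds per
group under minimal identification — referent loadings fixed to 1, the
first threshold of every item plus a second threshold of each referent
item equal across groups, factor means fixed to 0 everywhere, residual
variances fixed to 1 in the reference group only; (3) a scalar model
constrains all loadings and thresholds to equality, freeing factor means
and residual variances in non-reference groups. Scalar invariance is
supported when |delta CFI| <= 0.010 and |delta RMSEA| <= 0.015; the
adjusted chi-square difference test is reported alongside but is not
decisive (it is oversensitive at survey sample sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dwls import DiffTestResult, FitResult, difftest, fit_dwls
from .item_prep import MISSING, OrdinalItemMatrix, drop_collinear_items
from .model import FIXED, ModelSpec, ParamAllocator, Slot
from .polychoric import polychoric_matrix
from .structures import CFI_ACCEPT, RMSEA_ACCEPT

__all__ = ["InvarianceReport", "build_multigroup", "fit_per_group",
           "fit_configural", "fit_scalar", "invariance_decision",
           "run_invariance", "harmonize_categories"]

DELTA_CFI_RULE = 0.010
DELTA_RMSEA_RULE = 0.015


@dataclass
class InvarianceReport:
    per_group_fits: dict[str, FitResult]
    per_group_acceptable: dict[str, bool]
    configural_fit: FitResult
    scalar_fit: FitResult
    difftest: DiffTestResult
    delta_cfi: float
    delta_rmsea: float
    decision: str
    trace: list[str] = field(default_factory=list)
    dropped_items: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for g, f in self.per_group_fits.items():
            rows.append({"model": g, "chi2": f.chi2, "df": f.df,
                         "rmsea": f.rmsea, "cfi": f.cfi})
        for name, f in (("configural", self.configural_fit),
                        ("scalar", self.scalar_fit)):
            rows.append({"model": name, "chi2": f.chi2, "df": f.df,
                         "rmsea": f.rmsea, "cfi": f.cfi})
        rows.append({"model": "difftest", "chi2": self.difftest.chi2_diff,
                     "df": self.difftest.df_diff, "rmsea": self.delta_rmsea,
                     "cfi": self.delta_cfi})
        return pd.DataFrame(rows)


def _loading_pattern(kind: str, assignment, p: int):
    """(factor names, loads[j] = factor cols, referent[f] = item index)."""
    if kind == "one_factor":
        return ["general"], [[0] for _ in range(p)], {0: 0}
    assignment = np.asarray(assignment)
    m = int(assignment.max()) + 1
    if kind == "bifactor":
        factors = ["general"] + [f"sub{f + 1}" for f in range(m)]
        loads = [[0, 1 + assignment[j]] for j in range(p)]
        referent = {0: 0}
        used = {0}
        for f in range(m):
            # referent distinct from any already-used referent, so no item
            # carries two fixed loadings
            members = np.flatnonzero(assignment == f)
            fresh = [int(j) for j in members if int(j) not in used]
            choice = fresh[0] if fresh else int(members[0])
            referent[1 + f] = choice
            used.add(choice)
        return factors, loads, referent
    raise ValueError(f"multi-group invariance not supported for kind {kind!r}")


def build_multigroup(kind: str, assignment, items, n_categories, groups,
                     level: str) -> ModelSpec:
    """Configural or scalar multi-group ModelSpec (reference group = first)."""
    if level not in ("configural", "scalar"):
        raise ValueError("level must be 'configural' or 'scalar'")
    p = len(items)
    G = len(groups)
    factors, loads, referent = _loading_pattern(kind, assignment, p)
    referent_items = set(referent.values())
    m = len(factors)
    alloc = ParamAllocator()
    spec = ModelSpec(kind="cfa", items=list(items),
                     n_categories=list(n_categories), factors=factors,
                     groups=list(groups),
                     meta={"structure": kind, "level": level, "notes": []})

    # --- loadings -----------------------------------------------------
    shared_lam: dict[tuple[int, int], int] = {}
    for g in range(G):
        lam_idx = np.full((p, m), FIXED, dtype=int)
        lam_fix = np.zeros((p, m))
        for j in range(p):
            for f in loads[j]:
                if referent[f] == j:
                    lam_fix[j, f] = 1.0
                elif level == "scalar":
                    key = (j, f)
                    if key not in shared_lam:
                        shared_lam[key] = alloc.new(
                            f"lambda[{items[j]},{factors[f]}]", 0.5, lower=-8.0, upper=8.0)
                    lam_idx[j, f] = shared_lam[key]
                else:
                    lam_idx[j, f] = alloc.new(
                        f"lambda[{items[j]},{factors[f]}]:{groups[g]}", 0.5,
                        lower=-8.0, upper=8.0)
        spec.slots[(g, "lambda")] = Slot(lam_idx, lam_fix)

    # --- thresholds ---------------------------------------------------
    shared_tau: dict[tuple[int, int], int] = {}

    def tau_shared(j, c):
        key = (j, c)
        if key not in shared_tau:
            shared_tau[key] = alloc.new(f"tau[{items[j]},{c + 1}]", 0.0)
        return shared_tau[key]

    for g in range(G):
        idx, fix = [], []
        for j, k in enumerate(n_categories):
            for c in range(k - 1):
                if level == "scalar":
                    idx.append(tau_shared(j, c))
                elif c == 0:
                    idx.append(tau_shared(j, c))
                elif c == 1 and j in referent_items:
                    idx.append(tau_shared(j, c))
                else:
                    idx.append(alloc.new(
                        f"tau[{items[j]},{c + 1}]:{groups[g]}", 0.0))
                fix.append(0.0)
        spec.slots[(g, "tau")] = Slot(np.array(idx, dtype=int), np.array(fix))
    if level == "configural":
        for j in referent_items:
            if n_categories[j] < 3:
                spec.meta["notes"].append(
                    f"referent item {items[j]} is binary: no second "
                    f"threshold available for the cross-group constraint")

    # --- factor covariances, residual variances, means ----------------
    for g in range(G):
        psi_idx = np.full((m, m), FIXED, dtype=int)
        psi_fix = np.zeros((m, m))
        if kind == "bifactor" or kind == "one_factor":
            for f in range(m):
                psi_idx[f, f] = alloc.new(f"psi[{factors[f]}]:{groups[g]}",
                                          1.0, lower=1e-6)
        spec.slots[(g, "psi")] = Slot(psi_idx, psi_fix)

        if g == 0:
            spec.slots[(g, "theta")] = Slot.fixed(np.ones(p))
            spec.slots[(g, "alpha")] = Slot.fixed(np.zeros(m))
        else:
            th_idx = np.array([alloc.new(f"theta[{items[j]}]:{groups[g]}",
                                         1.0, lower=1e-6) for j in range(p)])
            spec.slots[(g, "theta")] = Slot(th_idx, np.ones(p))
            if level == "scalar":
                al_idx = np.array([alloc.new(
                    f"alpha[{factors[f]}]:{groups[g]}", 0.0) for f in range(m)])
                spec.slots[(g, "alpha")] = Slot(al_idx, np.zeros(m))
            else:
                spec.slots[(g, "alpha")] = Slot.fixed(np.zeros(m))
    return spec.finish(alloc)


def harmonize_categories(matrix: OrdinalItemMatrix, labels) -> OrdinalItemMatrix:
    """Merge categories that are empty within any group so that every group
    observes every category (required for per-group thresholds)."""
    values = matrix.values.copy()
    n_cats = list(matrix.n_categories)
    glabels = sorted(set(labels))
    changed = True
    while changed:
        changed = False
        for j in range(values.shape[1]):
            for g in glabels:
                rows = labels == g
                col = values[rows, j]
                obs = col[col != MISSING]
                counts = np.bincount(obs, minlength=n_cats[j])
                empty = np.flatnonzero(counts == 0)
                if empty.size and n_cats[j] > 2:
                    c = int(empty[0])
                    tgt = c + 1 if c + 1 < n_cats[j] else c - 1
                    warnings.warn(f"item {matrix.items[j]}: category {c} empty "
                                  f"in group {g}; merged into {tgt}")
                    colall = values[:, j]
                    obs_all = colall != MISSING
                    v = colall[obs_all]
                    lo = min(c, tgt)
                    v = np.where(v > lo, v - 1, v)
                    colall[obs_all] = v
                    values[:, j] = colall
                    n_cats[j] -= 1
                    changed = True
                    break
            if changed:
                break
    out = OrdinalItemMatrix(values=values, items=list(matrix.items),
                            n_categories=n_cats, group=matrix.group,
                            sex=matrix.sex, age_years=matrix.age_years,
                            extra=dict(matrix.extra))
    return out


def _group_summaries(matrix: OrdinalItemMatrix, group_var: str = "group"):
    labels = getattr(matrix, group_var) if group_var in ("group", "sex") \
        else matrix.extra[group_var]
    labels = np.asarray(labels)
    matrix = harmonize_categories(matrix, labels)
    order = sorted(set(labels.tolist()))
    summaries = {g: polychoric_matrix(matrix.subset(labels == g))
                 for g in order}
    return matrix, order, summaries


def fit_per_group(matrix: OrdinalItemMatrix, kind: str, assignment,
                  group_var: str = "group"):
    """Independent single-group fits of the shared structure; returns
    ``(fits, acceptable_flags, summaries, harmonized_matrix)``."""
    from .structures import build_structure
    matrix, order, summaries = _group_summaries(matrix, group_var)
    fits, ok = {}, {}
    for g in order:
        spec = build_structure(kind, assignment, matrix.items,
                               matrix.n_categories)
        fit = fit_dwls(summaries[g], spec)
        fits[g] = fit
        ok[g] = bool(fit.converged and fit.cfi is not None
                     and fit.cfi >= CFI_ACCEPT and fit.rmsea <= RMSEA_ACCEPT)
    return fits, ok, summaries, matrix


def _warm_start(spec: ModelSpec, per_group_fits: dict, order) -> np.ndarray:
    """Start values for a multi-group spec from single-group fits.

    Single-group fits identify factors by unit variances; the multi-group
    specs use referent loadings. The conversion divides each group's
    loading column by its referent loading and starts the factor variance
    at that referent loading squared. Parameters shared across groups
    start at the per-group average.
    """
    sums = np.zeros(spec.n_free)
    cnt = np.zeros(spec.n_free)

    def add(slot, vals):
        mask = slot.idx >= 0
        np.add.at(sums, slot.idx[mask], np.asarray(vals, dtype=float)[mask])
        np.add.at(cnt, slot.idx[mask], 1.0)

    for g, glabel in enumerate(order):
        est = per_group_fits[glabel].estimates(0)
        L = est["lambda"].copy()
        m = L.shape[1]
        lam_slot = spec.slot(g, "lambda")
        # referent item per factor: the fixed-to-1 cell
        scale = np.ones(m)
        for f in range(m):
            ref = np.flatnonzero((lam_slot.idx[:, f] == FIXED)
                                 & (lam_slot.fix[:, f] == 1.0))
            if ref.size:
                r = float(L[ref[0], f])
                scale[f] = r if abs(r) > 0.05 else 1.0
        add(lam_slot, L / scale)
        psi = est.get("psi", np.eye(m)) * np.outer(scale, scale)
        if (g, "psi") in spec.slots:
            add(spec.slot(g, "psi"), psi)
        for name in ("theta", "tau", "alpha"):
            if (g, name) in spec.slots and name in est:
                slot = spec.slots[(g, name)]
                if slot.idx.shape == np.shape(est[name]):
                    add(slot, est[name])
    start = spec.start.copy()
    got = cnt > 0
    start[got] = sums[got] / cnt[got]
    return start


def _fit_multigroup(summ, order, spec, warm_from) -> FitResult:
    """Fit with the better of the warm and default starts; retry from the
    other start when the first attempt fails or lands clearly higher."""
    from .model import implied_stat_vector
    summaries = [summ[g] for g in order]
    s = np.concatenate([sm.stat_vector() for sm in summaries])
    w = np.concatenate([sm.acov_diag for sm in summaries])

    def F_at(th):
        th = np.clip(th, spec.lower + 1e-10, spec.upper - 1e-10)
        return float(np.sum((implied_stat_vector(spec, th) - s) ** 2 / w))

    default = _set_tau_starts_default(spec, summaries)
    starts = [default]
    if warm_from:
        warm = _warm_start(spec, warm_from, order)
        if F_at(warm) < F_at(default):
            starts = [warm, default]
    fit = fit_dwls(summaries, spec, start_override=starts[0])
    for alt in starts[1:]:
        if fit.converged:
            break
        fit = fit_dwls(summaries, spec, start_override=alt)
    return fit


def _set_tau_starts_default(spec: ModelSpec, summaries) -> np.ndarray:
    from .dwls import _set_tau_starts
    return _set_tau_starts(spec, summaries, spec.start.copy())


def fit_configural(matrix: OrdinalItemMatrix, kind: str, assignment,
                   group_var: str = "group", summaries=None,
                   warm_from: dict | None = None) -> FitResult:
    matrix, order, summ = _group_summaries(matrix, group_var) \
        if summaries is None else (matrix, sorted(summaries), summaries)
    spec = build_multigroup(kind, assignment, matrix.items,
                            matrix.n_categories, order, "configural")
    return _fit_multigroup(summ, order, spec, warm_from)


def fit_scalar(matrix: OrdinalItemMatrix, kind: str, assignment,
               group_var: str = "group", summaries=None,
               warm_from: dict | None = None) -> FitResult:
    matrix, order, summ = _group_summaries(matrix, group_var) \
        if summaries is None else (matrix, sorted(summaries), summaries)
    spec = build_multigroup(kind, assignment, matrix.items,
                            matrix.n_categories, order, "scalar")
    return _fit_multigroup(summ, order, spec, warm_from)


def invariance_decision(configural: FitResult, scalar: FitResult,
                        dt: DiffTestResult | None = None):
    """Scalar invariance supported iff |delta CFI| <= 0.010 and
    |delta RMSEA| <= 0.015 (the difference test is reported, not decisive)."""
    if not (configural.converged and scalar.converged):
        raise ValueError("both multi-group fits must have converged")
    d_cfi = scalar.cfi - configural.cfi
    d_rmsea = scalar.rmsea - configural.rmsea
    eps = 1e-9  # boundary cases ("change of exactly 0.010") count as within
    ok = (abs(d_cfi) <= DELTA_CFI_RULE + eps
          and abs(d_rmsea) <= DELTA_RMSEA_RULE + eps)
    trace = [f"delta CFI = {d_cfi:+.4f} (rule: |.| <= {DELTA_CFI_RULE})",
             f"delta RMSEA = {d_rmsea:+.4f} (rule: |.| <= {DELTA_RMSEA_RULE})"]
    if dt is not None:
        trace.append(f"difftest chi2 = {dt.chi2_diff:.2f}, df = {dt.df_diff}, "
                     f"p = {dt.p_value:.3g} (reported, not decisive)")
    return ("supported" if ok else "rejected"), d_cfi, d_rmsea, trace


def run_invariance(matrix: OrdinalItemMatrix, kind: str, assignment,
                   group_var: str = "group",
                   collinear_r_max: float = 0.98) -> InvarianceReport:
    """Full three-step invariance protocol, preceded by the per-group
    collinearity screen."""
    labels = getattr(matrix, group_var) if group_var in ("group", "sex") \
        else matrix.extra[group_var]
    labels = np.asarray(labels)
    pre = harmonize_categories(matrix, labels)
    pre_summ = {g: polychoric_matrix(pre.subset(labels == g),
                                     compute_acov=False)
                for g in sorted(set(labels.tolist()))}
    dropped, kept, screen = drop_collinear_items(
        {g: s.R for g, s in pre_summ.items()}, pre.items, r_max=collinear_r_max)
    assignment = np.asarray(assignment)
    if dropped:
        keep_idx = [pre.items.index(it) for it in kept]
        assignment = assignment[keep_idx]
        # re-index subdomains in case one emptied out
        _, assignment = np.unique(assignment, return_inverse=True)
        matrix = pre.select_items(kept)
    else:
        matrix = pre

    fits, ok, summaries, matrix = fit_per_group(matrix, kind, assignment,
                                                group_var)
    order = sorted(summaries)
    conf = fit_configural(matrix, kind, assignment, summaries=summaries,
                          warm_from=fits)
    scal = fit_scalar(matrix, kind, assignment, summaries=summaries,
                      warm_from=fits)
    dt = difftest(scal, conf)
    decision, d_cfi, d_rmsea, trace = invariance_decision(conf, scal, dt)
    if dropped:
        trace.append(f"collinearity screen dropped: {dropped} "
                     f"({[s['r'] for s in screen]})")
    return InvarianceReport(per_group_fits=fits, per_group_acceptable=ok,
                            configural_fit=conf, scalar_fit=scal, difftest=dt,
                            delta_cfi=d_cfi, delta_rmsea=d_rmsea,
                            decision=decision, trace=trace,
                            dropped_items=dropped)
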