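"""End-to-end analysis pipeline: prepare -> split -> EFA -> structure
comparison -> measurement invariance -> bifactor indices -> MIMIC.

One config drives the whole run; every random step flows from the
config seed, so two runs with the same config produce identical
reports (timestamps excluded by construction: none are recorded).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dwls import fit_dwls
from .efa import assign_items, extract, parsimax_rotate
from .indices import bifactor_indices, standardized_bifactor
from .invariance import run_invariance
from .item_prep import (OrdinalItemMatrix, prepare_items, read_codebook,
                        read_matrix_csv, split_sample)
from .mimic import fit_mimic
from .polychoric import polychoric_matrix
from .simulate import fixture_latin6, simulate_bifactor_ordinal
from .structures import build_structure, compare_structures

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    fixture: str | None = "latin6"       # or None with input_csv/codebook set
    input_csv: str | None = None
    codebook: str | None = None
    n_scale: float = 1.0                 # shrink fixture group sizes
    frac_efa: float = 0.30
    n_factors: int = 4
    loading_cutoff: float = 0.20
    salient: float = 0.40
    merge_min_prop: float = 0.04
    collinear_r_max: float = 0.98
    invariance_groupings: tuple[str, ...] = ("group", "sex")
    bootstrap_B: int = 200
    seed: int = 0
    full_sample_cfa: bool = False        # deviation flag for power studies
    assignment: list[int] | None = None  # used when frac_efa == 0
    out_dir: str | None = None

    def validate(self):
        for name, v, lo, hi in [("frac_efa", self.frac_efa, 0, 0.9),
                                ("loading_cutoff", self.loading_cutoff, 0, 1),
                                ("salient", self.salient, 0, 1),
                                ("merge_min_prop", self.merge_min_prop, 0, 0.5),
                                ("collinear_r_max", self.collinear_r_max, 0.5, 1)]:
            if not lo <= v <= hi:
                raise ValueError(f"{name} = {v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path):
        data = yaml.safe_load(open(path)) or {}
        if "invariance_groupings" in data:
            data["invariance_groupings"] = tuple(data["invariance_groupings"])
        return cls(**data)


def _load_data(config: PipelineConfig) -> OrdinalItemMatrix:
    if config.fixture == "latin6":
        gen = fixture_latin6(seed=config.seed, n_scale=config.n_scale)
        return simulate_bifactor_ordinal(gen).matrix
    if config.input_csv and config.codebook:
        import pandas as pd
        codebook = read_codebook(config.codebook)
        df = pd.read_csv(config.input_csv)
        extra = tuple(c for c in ("srh", "ageband") if c in df.columns)
        mat, _ = prepare_items(df, codebook, min_prop=config.merge_min_prop,
                               extra_cols=extra)
        return mat
    raise ValueError("config needs a fixture name or input_csv + codebook")


def run_pipeline(config: PipelineConfig) -> dict:
    config.validate()
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(config).items()},
                    "stages": []}
    matrix = _load_data(config)
    report["n_persons"] = int(matrix.n)
    report["n_items"] = int(matrix.p)
    report["stages"].append("data")

    # ---- split ------------------------------------------------------
    if config.frac_efa > 0:
        split = split_sample(matrix, frac=config.frac_efa, seed=config.seed)
        efa_mat = matrix.subset(split.efa_ids)
        cfa_mat = matrix.subset(split.cfa_ids)
        report["split"] = {"n_efa": int(len(split.efa_ids)),
                           "n_cfa": int(len(split.cfa_ids))}
        report["stages"].append("split")
    else:
        efa_mat = None
        cfa_mat = matrix
        report["split"] = {"skipped": True,
                           "note": "frac_efa = 0: EFA stage skipped, using "
                                   "supplied item assignment"}
    if config.full_sample_cfa:
        cfa_mat = matrix
        report["split"]["full_sample_cfa"] = True

    # ---- EFA --------------------------------------------------------
    if efa_mat is not None:
        efa_summary = polychoric_matrix(efa_mat)
        sol = extract(efa_summary, config.n_factors)
        L_rot, Phi, crit = parsimax_rotate(sol.loadings_unrotated,
                                           seed=config.seed)
        sol.loadings_rotated, sol.factor_corr = L_rot, Phi
        assignment_info = assign_items(L_rot, cutoff=config.loading_cutoff,
                                       salient=config.salient)
        assignment = assignment_info.assignment
        report["efa"] = {
            "eigenvalues": np.round(sol.eigenvalues, 4).tolist(),
            "eigenvalue_ratio_1_2": float(sol.eigenvalues[0]
                                          / sol.eigenvalues[1]),
            "chi2": sol.fit.chi2, "df": sol.fit.df, "cfi": sol.fit.cfi,
            "rmsea": sol.fit.rmsea,
            "rotated_loadings": sol.rotated_table(efa_mat.items)
                .round(4).to_dict(),
            "non_congeneric": [efa_mat.items[i] for i in
                               np.flatnonzero(assignment_info.non_congeneric)],
            "near_tie": [efa_mat.items[i] for i in
                         np.flatnonzero(assignment_info.near_tie)],
            "assignment": assignment.tolist(),
        }
        report["stages"].append("efa")
    else:
        if config.assignment is None:
            raise ValueError("frac_efa = 0 requires an explicit assignment")
        assignment = np.asarray(config.assignment)

    # ---- structure comparison ---------------------------------------
    cfa_summary = polychoric_matrix(cfa_mat)
    fits = {}
    for kind in ("one_factor", "second_order", "bifactor"):
        spec = build_structure(kind, assignment, cfa_mat.items,
                               cfa_mat.n_categories)
        fits[kind] = fit_dwls(cfa_summary, spec)
    comparison = compare_structures(fits)
    report["cfa"] = {
        "table": comparison["table"].round(4).to_dict(orient="records"),
        "difftests": {k: {"chi2": t.chi2_diff, "df": t.df_diff,
                          "p": t.p_value}
                      for k, t in comparison["difftests"].items()},
        "selected": comparison["selected"], "tie": comparison["tie"],
    }
    report["stages"].append("cfa")
    selected = comparison["selected"] or "bifactor"

    # ---- measurement invariance -------------------------------------
    report["invariance"] = {}
    for gv in config.invariance_groupings:
        inv = run_invariance(cfa_mat, selected, assignment, group_var=gv,
                             collinear_r_max=config.collinear_r_max)
        report["invariance"][gv] = {
            "table": inv.table().round(4).to_dict(orient="records"),
            "decision": inv.decision,
            "delta_cfi": float(inv.delta_cfi),
            "delta_rmsea": float(inv.delta_rmsea),
            "dropped_items": inv.dropped_items,
            "trace": inv.trace,
        }
    report["stages"].append("invariance")

    # ---- bifactor indices -------------------------------------------
    if selected == "bifactor":
        lg, Ls, th = standardized_bifactor(fits["bifactor"])
        idx = bifactor_indices(lg, Ls, th)
        report["indices"] = {
            "omega": round(idx.omega_total, 4),
            "omega_h": round(idx.omega_h, 4),
            "omega_hs": np.round(idx.omega_hs, 4).tolist(),
            "ecv": round(idx.ecv, 4), "H": round(idx.H, 4),
            "general_share": round(idx.general_share, 4),
            "multidim_share": round(idx.multidim_share, 4),
            "error_share": round(idx.error_share, 4),
            "paragraph": idx.paragraph(),
        }
        report["stages"].append("indices")

    # ---- MIMIC ------------------------------------------------------
    if "srh" in cfa_mat.extra:
        mm = fit_mimic(cfa_mat, assignment, criterion="srh",
                       covariates=("sex", "ageband"),
                       n_bootstrap=config.bootstrap_B, seed=config.seed)
        report["mimic"] = {
            "beta_std": round(mm.beta_std, 4),
            "ci": [round(c, 4) for c in mm.ci] if mm.ci else None,
            "covariates": {k: round(v, 4)
                           for k, v in mm.covariate_betas_std.items()},
            "chi2": mm.fit.chi2, "df": mm.fit.df, "cfi": mm.fit.cfi,
            "rmsea": mm.fit.rmsea,
        }
        report["stages"].append("mimic")

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        with open(out / "report.txt", "w") as fh:
            fh.write(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Plain-text report: structure comparison, invariance tables,
    reliability paragraph, MIMIC result."""
    lines = ["Structure comparison",
             f"{'Model':<14}{'Chi-square':>12}{'df':>6}{'CFI':>8}"
             f"{'RMSEA':>8}  90% CI"]
    for r in report.get("cfa", {}).get("table", []):
        lines.append(f"{r['model']:<14}{r['chi2']:>12.2f}{r['df']:>6d}"
                     f"{r['cfi']:>8.3f}{r['rmsea']:>8.3f}  "
                     f"{r['rmsea_lo']:.3f}-{r['rmsea_hi']:.3f}")
    for name, t in report.get("cfa", {}).get("difftests", {}).items():
        lines.append(f"  difftest {name} vs bifactor: chi2 = {t['chi2']:.2f},"
                     f" df = {t['df']}, p = {t['p']:.3g}")
    lines.append(f"selected: {report.get('cfa', {}).get('selected')}")

    for gv, inv in report.get("invariance", {}).items():
        lines += ["", f"Measurement invariance by {gv} "
                      f"({inv['decision']}; dCFI {inv['delta_cfi']:+.4f}, "
                      f"dRMSEA {inv['delta_rmsea']:+.4f})",
                  f"{'Model':<14}{'Chi-square':>12}{'df':>6}{'RMSEA':>8}"
                  f"{'CFI':>8}"]
        for r in inv["table"]:
            lines.append(f"{str(r['model']):<14}{r['chi2']:>12.2f}"
                         f"{int(r['df']):>6d}{r['rmsea']:>8.3f}"
                         f"{r['cfi']:>8.3f}")

    if "indices" in report:
        lines += ["", report["indices"]["paragraph"]]
    if "mimic" in report:
        m = report["mimic"]
        ci = f" 95% CI {m['ci'][0]:.3f}-{m['ci'][1]:.3f}" if m["ci"] else ""
        lines += ["", f"MIMIC: standardized criterion effect = "
                      f"{m['beta_std']:.3f}{ci} "
                      f"(chi2 = {m['chi2']:.2f}, df = {m['df']}, "
                      f"CFI = {m['cfi']:.3f}, RMSEA = {m['rmsea']:.3f})"]
    return "\n".join(lines) + "\n"


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
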