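"""Item operationalisation: from raw mixed-type indicators to the oriented
ordinal item matrix the latent-variable models consume.

Continuous performance measures (e.g. time to walk 10 m, words recalled)
are cut at the pooled quartiles into three grades; after orientation the
top code always means *worst* health. Sparse response categories (< 4% of
the sample by default) are merged into the adjacent higher category so the
polychoric stage never sees empty or near-empty cells. An EFA/CFA split
stratified by sex and group, and a collinearity screen on per-group
polychoric matrices, complete the preparation stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

MISSING = -1

__all__ = [
    "MISSING",
    "CodebookEntry",
    "OrdinalItemMatrix",
    "SplitAssignment",
    "tertile_code",
    "merge_sparse_categories",
    "prepare_items",
    "split_sample",
    "drop_collinear_items",
    "read_codebook",
    "write_matrix_csv",
    "read_matrix_csv",
]


@dataclass
class CodebookEntry:
    """One raw indicator: how it is typed, oriented and sourced."""

    item_id: str
    dtype: str  # "ordinal" | "continuous"
    polarity: str  # "higher_is_worse" | "higher_is_better"
    n_categories: int | None = None
    source: str = ""

    def __post_init__(self):
        if self.dtype not in ("ordinal", "continuous"):
            raise ValueError(f"{self.item_id}: unknown dtype {self.dtype!r}")
        if self.polarity not in ("higher_is_worse", "higher_is_better"):
            raise ValueError(f"{self.item_id}: unknown polarity {self.polarity!r}")
        if self.dtype == "ordinal":
            if self.n_categories is None or self.n_categories < 2:
                raise ValueError(f"{self.item_id}: ordinal items need n_categories >= 2")


@dataclass
class OrdinalItemMatrix:
    """Person x item integer codes (0-based, ``MISSING`` marks missing),
    with grouping and covariate columns carried alongside."""

    values: np.ndarray  # (n, p) int
    items: list[str]
    n_categories: list[int]
    group: np.ndarray  # (n,) labels
    sex: np.ndarray  # (n,) 0/1
    age_years: np.ndarray  # (n,) float
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        for j, k in enumerate(self.n_categories):
            col = self.values[:, j]
            obs = col[col != MISSING]
            if obs.size and (obs.min() < 0 or obs.max() > k - 1):
                raise ValueError(f"item {self.items[j]}: code outside [0, {k - 1}]")

    def subset(self, rows) -> "OrdinalItemMatrix":
        rows = np.asarray(rows)
        return OrdinalItemMatrix(
            values=self.values[rows],
            items=list(self.items),
            n_categories=list(self.n_categories),
            group=self.group[rows],
            sex=self.sex[rows],
            age_years=self.age_years[rows],
            extra={k: v[rows] for k, v in self.extra.items()},
        )

    def select_items(self, keep: list[str]) -> "OrdinalItemMatrix":
        idx = [self.items.index(it) for it in keep]
        return OrdinalItemMatrix(
            values=self.values[:, idx],
            items=[self.items[i] for i in idx],
            n_categories=[self.n_categories[i] for i in idx],
            group=self.group,
            sex=self.sex,
            age_years=self.age_years,
            extra=dict(self.extra),
        )


@dataclass
class SplitAssignment:
    efa_ids: np.ndarray
    cfa_ids: np.ndarray
    strata: np.ndarray
    seed: int


def tertile_code(values, polarity: str, name: str = "item") -> np.ndarray:
    """Cut a continuous vector at its pooled quartiles into codes {0, 1, 2},
    oriented so that 2 = worst health.

    Values strictly below Q1 / strictly above Q3 form the outer grades;
    everything else (including exact ties with a quartile) is the middle
    grade. Quartiles use linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if obs.size < 4:
        raise ValueError(f"{name}: need >= 4 non-missing values for quartile coding")
    q1, q3 = np.quantile(obs, [0.25, 0.75])  # linear interpolation ("type 7")
    if q1 == q3:
        raise ValueError(f"{name}: degenerate distribution (Q1 == Q3 == {q1})")
    out = np.full(v.shape, MISSING, dtype=int)
    ok = ~np.isnan(v)
    mid = ok & (v >= q1) & (v <= q3)
    low = ok & (v < q1)
    high = ok & (v > q3)
    if polarity == "higher_is_worse":
        out[low], out[mid], out[high] = 0, 1, 2
    else:  # high performance = good health -> reverse
        out[low], out[mid], out[high] = 2, 1, 0
    return out


def merge_sparse_categories(codes, min_prop: float = 0.04, name: str = "item"):
    """Merge categories holding < ``min_prop`` of the non-missing sample into
    the adjacent higher category (the top category merges downward), repeating
    until every surviving category clears the floor.

    Returns ``(new_codes, log)`` where log records the merge steps and the
    before/after category counts. Collapse to a single category is an error:
    such an item carries no information.
    """
    codes = np.asarray(codes, dtype=int)
    obs_mask = codes != MISSING
    n_obs = int(obs_mask.sum())
    if n_obs == 0:
        raise ValueError(f"{name}: all values missing")
    k0 = int(codes[obs_mask].max()) + 1
    if k0 < 2:
        raise ValueError(f"{name}: fewer than 2 categories")
    # work on a category -> label mapping
    labels = list(range(k0))
    counts = [int(np.sum(codes[obs_mask] == c)) for c in labels]
    steps = []
    while True:
        k = len(counts)
        if k == 1:
            raise ValueError(f"{name}: merging collapsed the item to one category")
        sparse = [i for i in range(k) if counts[i] < min_prop * n_obs]
        if not sparse:
            break
        i = sparse[0]
        j = i + 1 if i + 1 < k else i - 1  # top category merges downward
        lo, hi = min(i, j), max(i, j)
        steps.append({"merged": labels[lo], "into": labels[hi], "count": counts[lo]})
        counts[hi] += counts[lo]
        del counts[lo], labels[lo]
    # relabel contiguous 0..K'-1 preserving order
    remap = np.full(k0, -1, dtype=int)
    for new, old in enumerate(labels):
        lo = 0 if new == 0 else labels[new - 1] + 1
        remap[lo : old + 1] = new
    out = codes.copy()
    out[obs_mask] = remap[codes[obs_mask]]
    log = {
        "item": name,
        "n_categories_before": k0,
        "n_categories_after": len(labels),
        "steps": steps,
        "counts_after": counts,
    }
    return out, log


def prepare_items(df: pd.DataFrame, codebook: list[CodebookEntry],
                  group_col: str = "group", sex_col: str = "sex",
                  age_col: str = "age_years", min_prop: float = 0.04,
                  extra_cols: tuple[str, ...] = ()):
    """Run the full preparation: quartile-code continuous items, orient all
    items so the top code is worst health, merge sparse categories.

    Returns ``(OrdinalItemMatrix, preparation_log)``.
    """
    n = len(df)
    values = np.empty((n, len(codebook)), dtype=int)
    n_cats, logs = [], []
    for j, entry in enumerate(codebook):
        raw = df[entry.item_id]
        if entry.dtype == "continuous":
            codes = tertile_code(raw.to_numpy(dtype=float), entry.polarity,
                                 name=entry.item_id)
        else:
            v = raw.to_numpy(dtype=float)
            codes = np.full(n, MISSING, dtype=int)
            ok = ~np.isnan(v)
            codes[ok] = v[ok].astype(int)
            if entry.polarity == "higher_is_better":
                codes[ok] = (entry.n_categories - 1) - codes[ok]
        codes, log = merge_sparse_categories(codes, min_prop=min_prop,
                                             name=entry.item_id)
        values[:, j] = codes
        n_cats.append(log["n_categories_after"])
        logs.append(log)
    mat = OrdinalItemMatrix(
        values=values,
        items=[e.item_id for e in codebook],
        n_categories=n_cats,
        group=df[group_col].to_numpy(),
        sex=df[sex_col].to_numpy(),
        age_years=df[age_col].to_numpy(dtype=float),
        extra={c: df[c].to_numpy() for c in extra_cols},
    )
    mat.validate()
    return mat, logs


def split_sample(matrix: OrdinalItemMatrix, frac: float = 0.30,
                 seed: int = 0) -> SplitAssignment:
    """Random split into an exploratory (``frac``) and a confirmatory
    (1 − ``frac``) sample, stratified by sex x group; deterministic given
    ``seed``."""
    rng = np.random.default_rng(seed)
    strata = np.array([f"{g}|{s}" for g, s in zip(matrix.group, matrix.sex)])
    efa_ids: list[int] = []
    pooled: list[int] = []
    for s in sorted(set(strata)):
        idx = np.flatnonzero(strata == s)
        if idx.size < 2:
            warnings.warn(f"stratum {s!r} has < 2 persons; sampling globally")
            pooled.extend(idx.tolist())
            continue
        take = int(round(frac * idx.size))
        efa_ids.extend(rng.choice(idx, size=take, replace=False).tolist())
    if pooled:
        take = int(round(frac * len(pooled)))
        efa_ids.extend(rng.choice(pooled, size=take, replace=False).tolist())
    efa = np.array(sorted(efa_ids), dtype=int)
    cfa = np.setdiff1d(np.arange(matrix.n), efa)
    return SplitAssignment(efa_ids=efa, cfa_ids=cfa, strata=strata, seed=seed)


def drop_collinear_items(poly_by_group: dict, items: list[str],
                         r_max: float = 0.98):
    """Screen per-group polychoric matrices for near-perfect pairs.

    For any within-group pair with |r| >= ``r_max`` the later item in
    codebook order is dropped from all groups. Returns
    ``(dropped_item_ids, kept_item_ids, report)``.
    """
    dropped: list[str] = []
    report = []
    for g, R in poly_by_group.items():
        R = np.asarray(R)
        p = R.shape[0]
        for i in range(p):
            for j in range(i + 1, p):
                if abs(R[i, j]) >= r_max:
                    victim = items[j]
                    report.append({"group": g, "pair": (items[i], items[j]),
                                   "r": float(R[i, j]), "dropped": victim})
                    if victim not in dropped:
                        dropped.append(victim)
    kept = [it for it in items if it not in dropped]
    return dropped, kept, report


# ---------------------------------------------------------------------------
# plain-text IO

def read_codebook(path) -> list[CodebookEntry]:
    text = open(path).read()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    return [CodebookEntry(**e) for e in data]


def write_matrix_csv(matrix: OrdinalItemMatrix, path) -> None:
    df = pd.DataFrame(matrix.values.astype(float), columns=matrix.items)
    df[df == MISSING] = np.nan
    df["group"] = matrix.group
    df["sex"] = matrix.sex
    df["age_years"] = matrix.age_years
    for k, v in matrix.extra.items():
        df[k] = v
    df.to_csv(path, index=False)


def read_matrix_csv(path, items: list[str], n_categories: list[int],
                    extra_cols: tuple[str, ...] = ()) -> OrdinalItemMatrix:
    df = pd.read_csv(path)
    values = np.full((len(df), len(items)), MISSING, dtype=int)
    for j, it in enumerate(items):
        v = df[it].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        values[ok, j] = v[ok].astype(int)
    mat = OrdinalItemMatrix(
        values=values, items=list(items), n_categories=list(n_categories),
        group=df["group"].to_numpy(), sex=df["sex"].to_numpy(),
        age_years=df["age_years"].to_numpy(dtype=float),
        extra={c: df[c].to_numpy() for c in extra_cols if c in df},
    )
    mat.validate()
    return mat
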