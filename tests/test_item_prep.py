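import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from ordifactor.item_prep import (MISSING, CodebookEntry, drop_collinear_items,
                                  merge_sparse_categories, prepare_items,
                                  split_sample, tertile_code)
from ordifactor.simulate import GeneratorConfig, simulate_bifactor_ordinal


def brute_force_tertile(values, polarity):
    """Sort-and-rank oracle: label each value against the interpolated
    quartiles computed from the sorted sample."""
    v = np.asarray(values, dtype=float)
    obs = np.sort(v[~np.isnan(v)])
    n = len(obs)

    def quantile(q):  # linear interpolation between order statistics
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return obs[lo] + (h - lo) * (obs[hi] - obs[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    out = np.full(v.shape, MISSING)
    for i, x in enumerate(v):
        if np.isnan(x):
            continue
        grade = 0 if x < q1 else (2 if x > q3 else 1)
        out[i] = grade if polarity == "higher_is_worse" else 2 - grade
    return out


class TestTertileCode:
    def test_higher_is_worse_orientation(self):
        v = np.arange(1.0, 101.0)  # e.g. seconds to walk 10 m
        codes = tertile_code(v, "higher_is_worse")
        q1, q3 = np.quantile(v, [0.25, 0.75])
        assert np.all(codes[v > q3] == 2)
        assert np.all(codes[v < q1] == 0)

    def test_higher_is_better_reverses(self):
        v = np.arange(1.0, 101.0)  # e.g. words recalled
        codes = tertile_code(v, "higher_is_better")
        q1, q3 = np.quantile(v, [0.25, 0.75])
        assert np.all(codes[v > q3] == 0)
        assert np.all(codes[v < q1] == 2)

    @given(st.lists(st.floats(-50, 50), min_size=8, max_size=60),
           st.sampled_from(["higher_is_worse", "higher_is_better"]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_agrees_with_sort_and_rank_oracle(self, values, polarity):
        v = np.asarray(values)
        if np.quantile(v, 0.25) == np.quantile(v, 0.75):
            return
        assert np.array_equal(tertile_code(v, polarity),
                              brute_force_tertile(v, polarity))

    def test_quartile_ties_go_to_middle(self):
        v = np.array([0.0, 1, 1, 1, 1, 1, 1, 2])  # Q1 == Q3 == 1 impossible
        v = np.array([0.0, 1, 2, 3, 4, 5, 6, 7, 8])
        codes = tertile_code(v, "higher_is_worse")
        q1 = np.quantile(v, 0.25)
        assert codes[v == q1][0] == 1  # exact tie with Q1 -> middle

    def test_degenerate_distribution_errors(self):
        with pytest.raises(ValueError, match="walk10m"):
            tertile_code(np.array([5.0] * 20), "higher_is_worse",
                         name="walk10m")

    def test_missing_propagates(self):
        v = np.array([1.0, np.nan, 3, 4, 5, 6, 7, 8])
        codes = tertile_code(v, "higher_is_worse")
        assert codes[1] == MISSING


class TestMergeSparseCategories:
    def test_middle_category_merges_upward(self):
        codes = np.repeat([0, 1, 2], [50, 3, 47])
        merged, log = merge_sparse_categories(codes)
        counts = np.bincount(merged)
        assert counts.tolist() == [50, 50]

    def test_exactly_four_percent_survives(self):
        codes = np.repeat([0, 1], [96, 4])
        merged, log = merge_sparse_categories(codes)
        assert np.array_equal(merged, codes)
        assert log["steps"] == []

    def test_merging_stops_at_fixed_point(self):
        codes = np.repeat([0, 1, 2], [2, 2, 96])
        merged, _ = merge_sparse_categories(codes)
        assert np.bincount(merged).tolist() == [4, 96]

    def test_top_category_merges_downward(self):
        codes = np.repeat([0, 1, 2], [50, 48, 2])
        merged, _ = merge_sparse_categories(codes)
        assert np.bincount(merged).tolist() == [50, 50]

    def test_collapse_to_single_category_errors(self):
        codes = np.repeat([0, 1], [2, 2])
        with pytest.raises(ValueError, match="one category"):
            merge_sparse_categories(codes, min_prop=0.9)

    @given(st.lists(st.integers(0, 4), min_size=30, max_size=300))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_every_surviving_category_clears_floor(self, codes):
        codes = np.asarray(codes)
        if len(np.unique(codes)) < 2:
            return
        # contiguous relabel of the raw draw
        _, codes = np.unique(codes, return_inverse=True)
        try:
            merged, _ = merge_sparse_categories(codes, min_prop=0.1)
        except ValueError:
            return  # collapsed: allowed outcome for extreme draws
        counts = np.bincount(merged[merged != MISSING])
        assert counts.min() >= 0.1 * len(codes)
        # codes relabelled contiguously, order preserved
        assert np.array_equal(np.unique(merged), np.arange(len(counts)))
        order = np.argsort(codes, kind="stable")
        assert np.all(np.diff(merged[order]) >= 0)


class TestSplitSample:
    def _matrix(self, n_per, groups=("a", "b"), seed=0):
        cfg = GeneratorConfig.simple(p=4, n_sub=1, lambda_sub=0.0,
                                     n_per_group=n_per, groups=groups,
                                     seed=seed)
        return simulate_bifactor_ordinal(cfg).matrix

    def test_exact_divisibility(self):
        mat = self._matrix((200, 200))
        split = split_sample(mat, frac=0.30, seed=1)
        strata = split.strata
        for s in set(strata):
            n_s = (strata == s).sum()
            got = np.isin(split.efa_ids, np.flatnonzero(strata == s)).sum()
            assert abs(got - 0.30 * n_s) <= 1

    def test_deterministic_given_seed(self):
        mat = self._matrix((300,), groups=("a",))
        s1 = split_sample(mat, 0.3, seed=5)
        s2 = split_sample(mat, 0.3, seed=5)
        assert np.array_equal(s1.efa_ids, s2.efa_ids)

    def test_frac_zero_gives_empty_efa(self):
        mat = self._matrix((100,), groups=("a",))
        split = split_sample(mat, frac=0.0, seed=0)
        assert len(split.efa_ids) == 0
        assert len(split.cfa_ids) == mat.n

    def test_partition_is_exact(self):
        mat = self._matrix((157, 211))
        split = split_sample(mat, 0.3, seed=2)
        union = np.union1d(split.efa_ids, split.cfa_ids)
        assert np.array_equal(union, np.arange(mat.n))
        assert len(np.intersect1d(split.efa_ids, split.cfa_ids)) == 0


class TestDropCollinear:
    def test_near_unity_pair_dropped_everywhere(self):
        R_ok = np.eye(3)
        R_bad = np.eye(3)
        R_bad[1, 2] = R_bad[2, 1] = 0.989  # the washing/dressing case
        dropped, kept, report = drop_collinear_items(
            {"g1": R_ok, "g6": R_bad}, ["a", "b", "c"])
        assert dropped == ["c"]          # later item in codebook order
        assert kept == ["a", "b"]
        assert report[0]["group"] == "g6"
        assert report[0]["r"] == pytest.approx(0.989)

    def test_all_below_threshold_is_noop(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.95
        dropped, kept, _ = drop_collinear_items({"g": R}, ["a", "b", "c"])
        assert dropped == []

    def test_threshold_is_closed(self):
        R = np.eye(2)
        R[0, 1] = R[1, 0] = 0.98
        dropped, _, _ = drop_collinear_items({"g": R}, ["a", "b"])
        assert dropped == ["b"]


def test_prepared_items_oriented_toward_worse_health():
    """After preparation every item correlates non-negatively with the
    generating 'worse health' factor."""
    cfg = GeneratorConfig.simple(p=6, n_sub=2, n_per_group=(2000,), seed=3)
    ds = simulate_bifactor_ordinal(cfg)
    for j in range(ds.matrix.p):
        col = ds.matrix.values[:, j]
        ok = col != MISSING
        rho = spearmanr(ds.eta_general[ok], col[ok]).statistic
        assert rho > 0


def test_prepare_items_full_path():
    """CSV-style table with a continuous item runs through coding,
    orientation and merging."""
    import pandas as pd
    rng = np.random.default_rng(0)
    n = 400
    df = pd.DataFrame({
        "walk_time": rng.exponential(10, n),
        "recall": rng.poisson(6, n).astype(float),
        "hearing": rng.choice([0, 1], n, p=[0.7, 0.3]).astype(float),
        "group": "x", "sex": rng.choice([0, 1], n), "age_years": 70.0,
    })
    codebook = [
        CodebookEntry("walk_time", "continuous", "higher_is_worse"),
        CodebookEntry("recall", "continuous", "higher_is_better"),
        CodebookEntry("hearing", "ordinal", "higher_is_worse", 2),
    ]
    mat, logs = prepare_items(df, codebook)
    assert mat.p == 3
    assert mat.n_categories[0] == 3
    mat.validate()
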