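import numpy as np
import pytest

from ordifactor.dwls import difftest, fit_dwls
from ordifactor.invariance import (build_multigroup, fit_configural,
                                   fit_per_group, fit_scalar,
                                   harmonize_categories, invariance_decision,
                                   run_invariance)
from ordifactor.item_prep import OrdinalItemMatrix
from ordifactor.polychoric import polychoric_matrix
from ordifactor.simulate import GeneratorConfig, simulate_bifactor_ordinal


@pytest.fixture(scope="module")
def invariance_run(twogroup_data):
    cfg, ds = twogroup_data
    return cfg, run_invariance(ds.matrix, "bifactor", cfg.subdomain,
                               group_var="group")


class TestDecisionRule:
    def _dummy(self, cfi, rmsea):
        import types
        f = types.SimpleNamespace(converged=True, cfi=cfi, rmsea=rmsea)
        return f

    def test_boundary_values_supported(self):
        conf = self._dummy(0.958, 0.046)
        scal = self._dummy(0.948, 0.056)  # dCFI = -0.010, dRMSEA = +0.010
        decision, d_cfi, d_rmsea, _ = invariance_decision(conf, scal)
        assert decision == "supported"
        assert d_cfi == pytest.approx(-0.010)

    def test_just_over_cfi_rule_rejected(self):
        conf = self._dummy(0.958, 0.046)
        scal = self._dummy(0.947, 0.046)  # dCFI = -0.011
        decision, *_ = invariance_decision(conf, scal)
        assert decision == "rejected"

    def test_zero_change_supported(self):
        conf = self._dummy(0.95, 0.04)
        decision, *_ = invariance_decision(conf, self._dummy(0.95, 0.04))
        assert decision == "supported"

    def test_rule_uses_magnitudes(self):
        # apparent *improvement* larger than the band still fails the rule
        conf = self._dummy(0.95, 0.055)
        scal = self._dummy(0.97, 0.035)  # dCFI = +0.020, dRMSEA = -0.020
        decision, *_ = invariance_decision(conf, scal)
        assert decision == "rejected"


class TestMultigroupFits:
    def test_identical_groups_give_symmetric_configural(self):
        """Two copies of the same data: configural estimates equal across
        groups."""
        cfg = GeneratorConfig.simple(p=6, n_sub=2, n_per_group=(1500,),
                                     seed=23)
        mat = simulate_bifactor_ordinal(cfg).matrix
        summ = polychoric_matrix(mat)
        spec = build_multigroup("bifactor", cfg.subdomain, mat.items,
                                mat.n_categories, ["a", "b"], "configural")
        fit = fit_dwls([summ, summ], spec)
        assert fit.converged
        # weakly identified directions can differ at parameter level;
        # the fitted (implied) moments must coincide across groups
        assert np.allclose(fit.implied_R[0], fit.implied_R[1], atol=2e-3)
        assert np.allclose(fit.residuals[0], fit.residuals[1], atol=2e-3)

    def test_configural_df_matches_hand_count(self):
        """6 items (3 cats), 2 groups, one-factor structure.

        Moments: 2 x (12 thresholds + 15 correlations) = 54.
        Free: loadings 2x5 (referent fixed) = 10; psi 2; theta group2 = 6;
        thresholds: item referent has both shared (2), others share first
        (5), second free per group (5 x 2) -> 2 + 5 + 10 = 17.
        Total free 35, df = 19.
        """
        spec = build_multigroup("one_factor", None,
                                [f"i{j}" for j in range(6)], [3] * 6,
                                ["a", "b"], "configural")
        assert spec.n_free == 35
        assert 54 - spec.n_free == 19

    def test_scalar_df_matches_hand_count(self):
        """Same toy, scalar: loadings 5 shared; psi 2; theta g2 6; alpha g2
        1; thresholds 12 shared -> 26 free, df = 28."""
        spec = build_multigroup("one_factor", None,
                                [f"i{j}" for j in range(6)], [3] * 6,
                                ["a", "b"], "scalar")
        assert spec.n_free == 26
        assert 54 - spec.n_free == 28

    def test_scalar_nested_in_configural(self, invariance_run):
        _, rep = invariance_run
        assert rep.scalar_fit.F_min >= rep.configural_fit.F_min - 1e-6
        assert rep.scalar_fit.df > rep.configural_fit.df
        assert rep.difftest.df_diff == rep.scalar_fit.df - rep.configural_fit.df

    def test_null_data_supports_invariance(self, invariance_run):
        _, rep = invariance_run
        assert rep.decision == "supported"
        assert all(rep.per_group_acceptable.values())

    def test_threshold_shift_rejected(self):
        cfg = GeneratorConfig.simple(
            p=9, n_sub=3, n_per_group=(1000, 1000), groups=("g1", "g2"),
            seed=77,
            noninvariance={"g2": {"threshold_shift": {j: 0.5
                                                      for j in range(6)}}})
        ds = simulate_bifactor_ordinal(cfg)
        rep = run_invariance(ds.matrix, "bifactor", cfg.subdomain,
                             group_var="group")
        assert rep.decision == "rejected"

    def test_planted_structure_violation_flagged_per_group(self):
        """A group whose true subdomain partition conflicts with the
        fitted one fails the per-group acceptability screen."""
        cfg = GeneratorConfig.simple(p=9, n_sub=3, n_per_group=(1000, 1000),
                                     groups=("g1", "g2"), seed=41,
                                     lambda_general=0.45, lambda_sub=0.6)
        ds = simulate_bifactor_ordinal(cfg)
        # regenerate group 2 with block partition [0,0,0,1,1,1,2,2,2]
        # (the fitted partition is interleaved [0,1,2,0,1,2,...])
        cfg_alt = GeneratorConfig.simple(p=9, n_sub=3, n_per_group=(1000,),
                                         groups=("g2",), seed=141,
                                         lambda_general=0.45, lambda_sub=0.6)
        cfg_alt.subdomain = np.repeat(np.arange(3), 3)
        ds_alt = simulate_bifactor_ordinal(cfg_alt)
        g2 = np.asarray(ds.matrix.group) == "g2"
        ds.matrix.values[g2] = ds_alt.matrix.values
        fits, ok, _, _ = fit_per_group(ds.matrix, "bifactor", cfg.subdomain)
        assert ok["g1"]
        assert not ok["g2"]

    def test_reference_group_permutation_equivalence(self):
        """Swapping which group is listed first leaves the scalar fit
        statistic essentially unchanged."""
        cfg = GeneratorConfig.simple(p=6, n_sub=2, n_per_group=(900, 900),
                                     groups=("g1", "g2"), seed=55)
        ds = simulate_bifactor_ordinal(cfg)
        labels = np.asarray(ds.matrix.group)
        summ = {g: polychoric_matrix(ds.matrix.subset(labels == g))
                for g in ("g1", "g2")}
        stats = {}
        for order in (["g1", "g2"], ["g2", "g1"]):
            spec = build_multigroup("bifactor", cfg.subdomain,
                                    ds.matrix.items, ds.matrix.n_categories,
                                    order, "scalar")
            stats[tuple(order)] = fit_dwls([summ[g] for g in order],
                                           spec).F_min
        a, b = stats.values()
        # the two identifications parameterize the same manifold; agreement
        # is limited only by optimizer termination
        assert a == pytest.approx(b, abs=0.02)

    def test_decision_invariant_to_group_label_permutation(self, twogroup_data):
        cfg, ds = twogroup_data
        relabel = {"g1": "zz_last", "g2": "aa_first"}
        mat = ds.matrix
        mat2 = OrdinalItemMatrix(
            values=mat.values, items=mat.items,
            n_categories=mat.n_categories,
            group=np.array([relabel[g] for g in mat.group]),
            sex=mat.sex, age_years=mat.age_years, extra=dict(mat.extra))
        rep2 = run_invariance(mat2, "bifactor", cfg.subdomain,
                              group_var="group")
        assert rep2.decision == "supported"


class TestHarmonize:
    def test_group_empty_category_merged_globally(self):
        rng = np.random.default_rng(0)
        values = rng.integers(0, 3, (200, 2))
        labels = np.repeat(["a", "b"], 100)
        values[100:, 0] = np.where(values[100:, 0] == 2, 1, values[100:, 0])
        mat = OrdinalItemMatrix(values, ["x", "y"], [3, 3], labels,
                                np.zeros(200), np.zeros(200))
        with pytest.warns(UserWarning, match="merged"):
            out = harmonize_categories(mat, labels)
        assert out.n_categories[0] == 2
        assert out.n_categories[1] == 3

    def test_collinear_drop_before_invariance(self):
        """A duplicated item is removed by the collinearity screen and the
        protocol still runs."""
        cfg = GeneratorConfig.simple(p=6, n_sub=2, n_per_group=(800, 800),
                                     groups=("g1", "g2"), seed=19)
        ds = simulate_bifactor_ordinal(cfg)
        mat = ds.matrix
        dup = mat.values[:, 2].copy()
        values = np.column_stack([mat.values, dup])
        mat2 = OrdinalItemMatrix(values, mat.items + ["item_dup"],
                                 mat.n_categories + [mat.n_categories[2]],
                                 mat.group, mat.sex, mat.age_years)
        assignment = np.concatenate([cfg.subdomain, [cfg.subdomain[2]]])
        rep = run_invariance(mat2, "bifactor", assignment, group_var="group")
        assert rep.dropped_items == ["item_dup"]
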