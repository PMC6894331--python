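import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist
from scipy.stats import ncx2

from ordifactor.dwls import difftest, fit_dwls, fit_indices
from ordifactor.model import (FIXED, ModelSpec, ParamAllocator, Slot,
                              implied_stat_vector)
from ordifactor.polychoric import polychoric_matrix
from ordifactor.simulate import GeneratorConfig, simulate_bifactor_ordinal
from ordifactor.structures import build_structure
from ordifactor.dwls import residual_matrix
from conftest import true_raw_loadings


def fixed_loading_spec(loadings, theta, n_categories, psi=None):
    """Spec with every structural parameter fixed (free thresholds only)."""
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    if loadings.shape[0] == 1:
        loadings = loadings.T
    p, m = loadings.shape
    items = [f"i{j}" for j in range(p)]
    alloc = ParamAllocator()
    spec = ModelSpec(kind="cfa", items=items, n_categories=list(n_categories),
                     factors=[f"f{k}" for k in range(m)], groups=["all"])
    spec.slots[(0, "lambda")] = Slot.fixed(loadings)
    spec.slots[(0, "psi")] = Slot.fixed(psi if psi is not None else np.eye(m))
    spec.slots[(0, "theta")] = Slot.fixed(np.asarray(theta, dtype=float))
    spec.slots[(0, "alpha")] = Slot.fixed(np.zeros(m))
    idx, fix = [], []
    for it, k in zip(items, n_categories):
        for c in range(k - 1):
            idx.append(alloc.new(f"tau[{it},{c}]", 0.0))
            fix.append(0.0)
    spec.slots[(0, "tau")] = Slot(np.array(idx), np.array(fix))
    return spec.finish(alloc)


class TestImpliedMoments:
    def test_zero_loadings_imply_identity(self):
        spec = fixed_loading_spec(np.zeros(3), np.ones(3), [3, 3, 3])
        sig = implied_stat_vector(spec, spec.start)
        assert np.allclose(sig[-3:], 0.0)  # the three correlations

    def test_loading_product_closed_form(self):
        lam = np.array([0.6, 0.8])
        theta = 1.0 - lam**2  # unit latent-response variances
        spec = fixed_loading_spec(lam, theta, [3, 3])
        sig = implied_stat_vector(spec, spec.start)
        assert sig[-1] == pytest.approx(0.48, abs=1e-12)

    def test_matches_monte_carlo_covariance(self):
        """Implied correlations equal the Monte-Carlo correlation matrix of
        simulated latent responses under the same parameters."""
        rng = np.random.default_rng(0)
        lam = np.array([[0.7, 0.3], [0.5, 0.4], [0.6, 0.0], [0.4, 0.5]])
        theta = np.array([0.8, 1.2, 1.0, 0.9])
        spec = fixed_loading_spec(lam, theta, [2, 2, 2, 2])
        sig = implied_stat_vector(spec, spec.start)
        n = 400_000
        eta = rng.standard_normal((n, 2))
        y = eta @ lam.T + rng.standard_normal((n, 4)) * np.sqrt(theta)
        emp = np.corrcoef(y.T)
        iu = np.triu_indices(4, 1)
        assert np.allclose(sig[-6:], emp[iu], atol=0.01)

    def test_theta_equals_delta_for_unit_variance_solution(self):
        """With residual variances fixed so latent responses have unit
        variance, implied moments match the delta-parameterization closed
        form lambda_j lambda_k for a one-factor model."""
        lam = np.array([0.5, 0.6, 0.7])
        spec = fixed_loading_spec(lam, 1 - lam**2, [3, 3, 3])
        sig = implied_stat_vector(spec, spec.start)
        expect = np.outer(lam, lam)[np.triu_indices(3, 1)]
        assert np.allclose(sig[-3:], expect, atol=1e-12)


class TestFitDwls:
    def test_parameter_recovery_one_factor(self, onefactor_data):
        cfg, _, summary = onefactor_data
        spec = build_structure("one_factor", None, summary.items,
                               summary.n_categories)
        fit = fit_dwls(summary, spec)
        assert fit.converged
        lam_true, _ = true_raw_loadings(cfg)
        est = fit.estimates(0)["lambda"][:, 0]
        lam_se = fit.se[:5]
        assert np.all(np.abs(np.abs(est) - lam_true) < 4 * lam_se)

    def test_saturated_model_zero_discrepancy(self, onefactor_data):
        _, _, summary = onefactor_data
        sub = None
        # 3 items, one factor: 3 free loadings vs 3 correlations -> df = 0
        from ordifactor.item_prep import OrdinalItemMatrix
        spec = build_structure("one_factor", sub, summary.items[:3],
                               summary.n_categories[:3])
        import copy
        small = _subset_summary(summary, [0, 1, 2])
        fit = fit_dwls(small, spec)
        assert fit.df == 0
        assert fit.F_min == pytest.approx(0.0, abs=1e-10)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)

    def test_estimates_invariant_to_item_order(self, onefactor_data):
        _, ds, _ = onefactor_data
        perm = [3, 0, 4, 1, 2]
        mat = ds.matrix
        mat_p = mat.select_items([mat.items[i] for i in perm])
        f1 = fit_dwls(polychoric_matrix(mat),
                      build_structure("one_factor", None, mat.items,
                                      mat.n_categories))
        f2 = fit_dwls(polychoric_matrix(mat_p),
                      build_structure("one_factor", None, mat_p.items,
                                      mat_p.n_categories))
        l1 = np.abs(f1.estimates(0)["lambda"][:, 0])
        l2 = np.abs(f2.estimates(0)["lambda"][:, 0])
        assert np.allclose(l1[perm], l2, atol=1e-4)

    def test_chi2_calibrated_under_correct_model(self):
        """Adjusted statistic rejects a correct model at ~nominal rate
        (a slice of the full calibration run in the acceptance suite)."""
        rej = 0
        n_rep = 60
        for r in range(n_rep):
            cfg = GeneratorConfig.simple(p=5, n_sub=1, lambda_general=0.6,
                                         lambda_sub=0.0, n_per_group=(500,),
                                         seed=7000 + r)
            summ = polychoric_matrix(simulate_bifactor_ordinal(cfg).matrix)
            spec = build_structure("one_factor", None, summ.items,
                                   summ.n_categories)
            fit = fit_dwls(summ, spec)
            rej += chi2_dist.sf(fit.chi2, fit.df) < 0.05
        assert 0 <= rej / n_rep <= 0.15


class TestFitIndices:
    def test_perfect_fit_limit(self):
        cfi, rmsea, ci = fit_indices(100.0, 100, 500.0, 120, n=1000)
        assert cfi == 1.0
        assert rmsea == 0.0

    def test_rmsea_closed_form(self):
        cfi, rmsea, _ = fit_indices(200.0, 100, 2000.0, 120, n=1000)
        assert rmsea == pytest.approx(np.sqrt(100 / 100_000), abs=1e-12)

    def test_ci_inverts_noncentral_chi_square(self):
        T, df, n = 180.0, 100, 800
        _, _, (lo, hi) = fit_indices(T, df, 2000.0, 120, n=n)
        lam_lo = lo**2 * df * n
        lam_hi = hi**2 * df * n
        assert ncx2.cdf(T, df, lam_lo) == pytest.approx(0.95, abs=1e-6)
        assert ncx2.cdf(T, df, lam_hi) == pytest.approx(0.05, abs=1e-6)

    def test_df_zero_reports_undefined(self):
        assert fit_indices(0.0, 0, 10.0, 3, n=100) == (None, None, None)


class TestResiduals:
    def test_symmetric_zero_diagonal(self, onefactor_data):
        _, _, summary = onefactor_data
        spec = build_structure("one_factor", None, summary.items,
                               summary.n_categories)
        fit = fit_dwls(summary, spec)
        R = fit.residuals[0]
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 0.0)

    def test_planted_cross_loading_localizes(self):
        """Omitting a true extra dependence between two items puts the
        largest residual on exactly that pair."""
        cfg = GeneratorConfig.simple(p=6, n_sub=1, lambda_general=0.55,
                                     lambda_sub=0.0, n_per_group=(3000,),
                                     seed=31)
        ds = simulate_bifactor_ordinal(cfg)
        vals = ds.matrix.values.copy()
        # plant association: item 5 partially copies item 4
        rng = np.random.default_rng(1)
        copy_mask = rng.random(ds.n) < 0.15
        vals[copy_mask, 5] = vals[copy_mask, 4]
        mat = ds.matrix
        mat.values = vals
        fit = fit_dwls(polychoric_matrix(mat),
                       build_structure("one_factor", None, mat.items,
                                       mat.n_categories))
        _, report = residual_matrix(fit)
        top_pair = {report.iloc[0]["item_1"], report.iloc[0]["item_2"]}
        assert top_pair == {"item05", "item06"}


class TestDifftest:
    def test_identical_specs_not_nested(self, onefactor_data):
        _, _, summary = onefactor_data
        spec = build_structure("one_factor", None, summary.items,
                               summary.n_categories)
        fit = fit_dwls(summary, spec)
        with pytest.raises(ValueError, match="not nested"):
            difftest(fit, fit)

    def test_different_data_rejected(self, onefactor_data, bifactor_data):
        _, _, s1 = onefactor_data
        _, _, s2 = bifactor_data
        f1 = fit_dwls(s1, build_structure("one_factor", None, s1.items,
                                          s1.n_categories))
        f2 = fit_dwls(s2, build_structure("one_factor", None, s2.items,
                                          s2.n_categories))
        with pytest.raises(ValueError, match="same data"):
            difftest(f1, f2)

    def test_onefactor_vs_bifactor_power(self, bifactor_data):
        cfg, _, summary = bifactor_data
        f_bi = fit_dwls(summary, build_structure("bifactor", cfg.subdomain,
                                                 summary.items,
                                                 summary.n_categories))
        f_one = fit_dwls(summary, build_structure("one_factor", None,
                                                  summary.items,
                                                  summary.n_categories))
        dt = difftest(f_one, f_bi)
        assert dt.df_diff == f_one.df - f_bi.df
        assert dt.p_value < 0.001

    def test_nesting_monotone_discrepancy(self, bifactor_data):
        cfg, _, summary = bifactor_data
        fits = {k: fit_dwls(summary, build_structure(
            k, cfg.subdomain if k != "one_factor" else None,
            summary.items, summary.n_categories))
            for k in ("one_factor", "second_order", "bifactor")}
        assert fits["one_factor"].F_min >= fits["second_order"].F_min - 1e-6
        assert fits["second_order"].F_min >= fits["bifactor"].F_min - 1e-6


def _subset_summary(summary, keep):
    """Restrict a PolychoricSummary to a subset of items (test helper)."""
    import copy
    keep = list(keep)
    pairs = summary.pairs
    sel_pairs = [i for i, (j, k) in enumerate(pairs)
                 if j in keep and k in keep]
    q_t_offsets = np.cumsum([0] + [len(t) for t in summary.thresholds])
    tau_rows = np.concatenate([np.arange(q_t_offsets[j], q_t_offsets[j + 1])
                               for j in keep])
    rows = np.concatenate([tau_rows,
                           q_t_offsets[-1] + np.asarray(sel_pairs)]).astype(int)
    new = copy.copy(summary)
    new.items = [summary.items[j] for j in keep]
    new.n_categories = [summary.n_categories[j] for j in keep]
    new.thresholds = [summary.thresholds[j] for j in keep]
    new.R = summary.R[np.ix_(keep, keep)]
    new.R_pd = summary.R_pd[np.ix_(keep, keep)]
    new.n_pairwise = summary.n_pairwise[np.ix_(keep, keep)]
    new.acov_full = summary.acov_full[np.ix_(rows, rows)]
    new.acov_diag = summary.acov_diag[rows]
    return new
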