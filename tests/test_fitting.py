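import warnings

import numpy as np
import pandas as pd
import pytest

from cardiocirc import (ARModel, DEFAULT_COEFFICIENTS, CircadianCoefficients,
                        SimulationSpec, SubjectProfile, backward_eliminate,
                        cluster_robust_covariance, fit_ar_residuals,
                        fit_circadian_model, fit_preliminary_model,
                        goodness_of_fit, robust_refit, simulate_ar_noise,
                        simulate_subject_rr, visual_predictive_check)
from cardiocirc.fitting import (EstimationError, FINAL_TERMS, cluster_sandwich,
                                stack_series)


def simulate_cohort(subjects, coeffs, ar, times, seed):
    spec = SimulationSpec(coeffs, ar, times, seed=seed)
    return [simulate_subject_rr(spec, s) for s in subjects]


class TestFitCircadianModel:
    def test_noise_free_recovery(self, mixed_cohort, noiseless_coeffs, silent_ar,
                                 hour_grid):
        data = simulate_cohort(mixed_cohort, noiseless_coeffs, silent_ar,
                               hour_grid, seed=0)
        fit = fit_circadian_model(data)
        np.testing.assert_allclose(fit.coefficients.as_array(),
                                   noiseless_coeffs.as_array(), atol=1e-8)
        assert fit.sigma == pytest.approx(0.0, abs=1e-8)

    def test_single_subject_rejected(self, hour_grid, noiseless_coeffs, silent_ar):
        data = simulate_cohort([SubjectProfile("only", 0, 30.0)], noiseless_coeffs,
                               silent_ar, hour_grid, seed=0)
        with pytest.raises(EstimationError):
            fit_circadian_model(data)

    def test_single_sex_design_names_collinear_terms(self, hour_grid,
                                                     noiseless_coeffs, silent_ar):
        females = [SubjectProfile(f"f{i}", 0, 20.0 + 5 * i) for i in range(4)]
        data = simulate_cohort(females, noiseless_coeffs, silent_ar, hour_grid, 0)
        with pytest.raises(EstimationError, match="sex"):
            fit_circadian_model(data)

    def test_sigma_estimates_marginal_residual_sd(self, mixed_cohort, white_noise_ar):
        data = simulate_cohort(mixed_cohort, DEFAULT_COEFFICIENTS, white_noise_ar,
                               np.linspace(0, 24, 1441)[:-1], seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_circadian_model(data)
        assert fit.sigma == pytest.approx(0.15, rel=0.03)


class TestClusterRobustCovariance:
    @staticmethod
    def _random_clustered(n_groups, per_group, seed):
        rng = np.random.default_rng(seed)
        g = np.repeat(np.arange(n_groups), per_group)
        x = rng.normal(size=g.size)
        u = rng.normal(size=n_groups)[g] + rng.normal(size=g.size)
        y = 1.0 + 2.0 * x + u
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return X, y - X @ beta, g

    def test_cr1_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        g = np.repeat(np.arange(25), 40)
        x = rng.normal(size=g.size)
        y = 1.0 + 2.0 * x + rng.normal(size=25)[g] + rng.normal(size=g.size)
        X = np.column_stack([np.ones_like(x), x])
        res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": g})
        mine = cluster_sandwich(X, np.asarray(res.resid), g, kind="CR1")
        np.testing.assert_allclose(mine, res.cov_params(), rtol=1e-8)

    def test_singleton_clusters_close_to_classical_ols(self):
        rng = np.random.default_rng(0)
        n = 5000
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        classical = (resid @ resid / (n - 2)) * np.linalg.inv(X.T @ X)
        scale = np.sqrt(np.outer(np.diag(classical), np.diag(classical)))
        for kind in ("CR1", "CR2"):
            robust = cluster_sandwich(X, resid, np.arange(n), kind=kind)
            np.testing.assert_allclose(robust / scale, classical / scale,
                                       rtol=0.10, atol=0.05)

    def test_duplicating_clusters_leaves_robust_se_stable(self):
        X, resid, g = self._random_clustered(20, 30, seed=5)
        V1 = cluster_sandwich(X, resid, g, kind="CR1")
        X2 = np.vstack([X, X])
        resid2 = np.concatenate([resid, resid])
        g2 = np.concatenate([g, g])
        V2 = cluster_sandwich(X2, resid2, g2, kind="CR1")
        # duplicated clusters: robust SEs essentially unchanged ...
        np.testing.assert_allclose(np.sqrt(np.diag(V2)), np.sqrt(np.diag(V1)),
                                   rtol=0.02)
        # ... while the naive iid covariance shrinks by sqrt(2)
        naive1 = (resid @ resid / (len(g) - 2)) * np.linalg.inv(X.T @ X)
        naive2 = (resid2 @ resid2 / (len(g2) - 2)) * np.linalg.inv(X2.T @ X2)
        np.testing.assert_allclose(np.sqrt(np.diag(naive2)),
                                   np.sqrt(np.diag(naive1)) / np.sqrt(2), rtol=0.01)

    def test_single_cluster_warns(self):
        X, resid, _ = self._random_clustered(2, 20, seed=6)
        with pytest.warns(UserWarning):
            cluster_sandwich(X, resid, np.zeros(len(resid), dtype=int))

    def test_recompute_from_fit_matches_stored(self, mixed_cohort, white_noise_ar,
                                               hour_grid):
        data = simulate_cohort(mixed_cohort, DEFAULT_COEFFICIENTS, white_noise_ar,
                               hour_grid, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_circadian_model(data)
            V = cluster_robust_covariance(fit)
        np.testing.assert_allclose(V, fit.covariance.to_numpy())


class TestBackwardElimination:
    @staticmethod
    def _cohort_without_sex_interactions(seed):
        truth = CircadianCoefficients(7.163, 0.0961, -0.0243, 0.00027,
                                      0.1055, 0.0664, 0.0, 0.0, sigma=0.02)
        subjects = [SubjectProfile(f"s{i}", i % 2, 20.0 + 2.5 * i) for i in range(12)]
        return simulate_cohort(subjects, truth, ARModel((), 0.02),
                               np.linspace(0, 24, 241)[:-1], seed)

    def test_null_interactions_dropped_main_effects_kept(self):
        data = self._cohort_without_sex_interactions(seed=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_circadian_model(data)
            reduced = backward_eliminate(fit, alpha=0.05)
        assert "sin:sex" not in reduced.terms and "cos:sex" not in reduced.terms
        for term in ("sex", "age", "sin", "cos"):
            assert term in reduced.terms

    def test_alpha_one_drops_nothing(self):
        data = self._cohort_without_sex_interactions(seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_circadian_model(data)
            assert backward_eliminate(fit, alpha=1.0).terms == fit.terms

    def test_fixed_point_when_all_significant(self, mixed_cohort, hour_grid):
        data = simulate_cohort(mixed_cohort, DEFAULT_COEFFICIENTS, ARModel((), 0.01),
                               hour_grid, seed=12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_circadian_model(data)
            if (fit.p_values.drop("const") <= 0.05).all():
                assert backward_eliminate(fit, alpha=0.05).terms == fit.terms

    def test_hierarchy_respected_from_preliminary_model(self):
        subjects = [SubjectProfile(f"s{i}", i % 2, 20.0 + 4.0 * i) for i in range(8)]
        data = simulate_cohort(subjects, DEFAULT_COEFFICIENTS, ARModel((), 0.1),
                               np.linspace(0, 24, 97)[:-1], seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pre = fit_preliminary_model(data)
            reduced = backward_eliminate(pre, alpha=0.05)
        present = set(reduced.terms)
        for term in present:
            if ":" in term:
                for parent in term.split(":"):
                    assert parent in present, f"{term} kept without {parent}"
        assert "const" in present


def test_preliminary_hourly_profile_traces_cosinor(mixed_cohort):
    """Hourly-dummy fit loses almost no log-scale R^2 vs the cosinor form."""
    data = [simulate_subject_rr(
        SimulationSpec(DEFAULT_COEFFICIENTS, ARModel((), 0.15),
                       np.linspace(0, 24, 1441)[:-1], seed=14), s)
        for s in mixed_cohort]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pre = fit_preliminary_model(data)
        final = fit_circadian_model(data)
    r2_pre = pre.diagnostics["r_squared_log"]
    r2_final = final.diagnostics["r_squared_log"]
    assert r2_pre - r2_final < 0.01  # dummies buy < 1% absolute R^2


class TestRobustRefit:
    def _clean_data(self, mixed_cohort, seed=20):
        return [simulate_subject_rr(
            SimulationSpec(DEFAULT_COEFFICIENTS, ARModel((), 0.02),
                           np.linspace(0, 24, 481)[:-1], seed=seed), s)
            for s in mixed_cohort]

    def test_agrees_with_least_squares_on_clean_data(self, mixed_cohort):
        data = self._clean_data(mixed_cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = fit_circadian_model(data).coefficients.as_array()
        rob = robust_refit(data).as_array()
        np.testing.assert_allclose(rob, ols, rtol=5e-3, atol=2e-4)

    def test_resists_gross_outliers(self, mixed_cohort):
        data = self._clean_data(mixed_cohort, seed=21)
        rng = np.random.default_rng(0)
        for s in data:  # 1% of beats multiplied by 10
            idx = rng.choice(len(s), size=max(1, len(s) // 100), replace=False)
            s.rr_ms[idx] *= 10.0
        rob = robust_refit(data).as_array()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = fit_circadian_model(data).coefficients.as_array()
        true = DEFAULT_COEFFICIENTS.as_array()
        assert abs(rob[0] - true[0]) < abs(ols[0] - true[0])
        assert abs(rob[0] - true[0]) / true[0] < 0.02

    def test_empty_data_rejected(self):
        with pytest.raises(EstimationError):
            robust_refit([])


class TestFitARResiduals:
    def test_white_noise_alphas_near_zero(self):
        rng = np.random.default_rng(30)
        resid = [rng.normal(0, 0.1, size=5000) for _ in range(4)]
        ar = fit_ar_residuals(resid, order=5)
        assert np.all(np.abs(ar.alphas_array) < 0.05)
        assert ar.tau == pytest.approx(0.1, rel=0.02)

    def test_ar2_parameter_recovery(self):
        eps = simulate_ar_noise(ARModel((0.5, 0.3), 0.1), 50_000, seed=31)
        ar = fit_ar_residuals([eps], order=2)
        np.testing.assert_allclose(ar.alphas_array, [0.5, 0.3], atol=0.02)
        assert ar.tau == pytest.approx(0.1, rel=0.02)

    def test_overfitting_extra_lags_are_null(self):
        eps = simulate_ar_noise(ARModel((0.5, 0.3), 0.1), 50_000, seed=32)
        ar = fit_ar_residuals([eps], order=5)
        np.testing.assert_allclose(ar.alphas_array[2:], 0.0, atol=0.03)

    def test_order_zero_gives_white_noise_model(self):
        rng = np.random.default_rng(33)
        ar = fit_ar_residuals([rng.normal(0, 0.2, 1000)], order=0)
        assert ar.order == 0
        assert ar.tau == pytest.approx(0.2, rel=0.05)

    def test_short_series_excluded_with_warning(self):
        rng = np.random.default_rng(34)
        good = rng.normal(0, 0.1, 500)
        with pytest.warns(UserWarning, match="excluded"):
            ar = fit_ar_residuals([good, np.zeros(3)], order=5)
        assert ar.order == 5
        with pytest.raises(EstimationError):
            fit_ar_residuals([np.zeros(3)], order=5)

    def test_boundaries_never_cross_subjects(self):
        # two constant-but-different subjects: pooled AR(1) on the stacked
        # series would see a jump; boundary-respecting fit must not
        a = np.full(300, 0.5) + simulate_ar_noise(ARModel((), 0.01), 300, seed=35)
        b = np.full(300, -0.5) + simulate_ar_noise(ARModel((), 0.01), 300, seed=36)
        ar = fit_ar_residuals([a, b], order=1)
        naive = fit_ar_residuals([np.concatenate([a, b])], order=1)
        assert ar.alphas[0] == pytest.approx(1.0, abs=0.02)  # mean offsets dominate
        assert ar.tau < naive.tau  # the cross-boundary jump inflates naive tau


class TestGoodnessOfFit:
    def test_hand_values(self):
        m = goodness_of_fit([100.0, 200.0], [110.0, 190.0])
        assert m["rmse_ms"] == pytest.approx(10.0)
        # |−10|/100 = 10%, |20|/200 = 10% -> mean 10%
        m = goodness_of_fit([100.0, 200.0], [110.0, 180.0])
        assert m["mape_percent"] == pytest.approx(10.0)

    def test_perfect_fit(self):
        m = goodness_of_fit([800.0, 900.0, 1000.0], [800.0, 900.0, 1000.0])
        assert m == {"rmse_ms": 0.0, "mape_percent": 0.0, "r_squared_log": 1.0}

    def test_r2_invariant_to_rescaling(self):
        rng = np.random.default_rng(40)
        obs = rng.uniform(600, 1200, 100)
        pred = obs * rng.uniform(0.9, 1.1, 100)
        r2 = goodness_of_fit(obs, pred)["r_squared_log"]
        r2_scaled = goodness_of_fit(obs * 3.7, pred * 3.7)["r_squared_log"]
        assert r2 == pytest.approx(r2_scaled, abs=1e-12)

    def test_input_errors(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            goodness_of_fit([-1.0, 2.0], [1.0, 2.0])


class TestVisualPredictiveCheck:
    def _small_data(self, mixed_cohort, ar, seed=50):
        return [simulate_subject_rr(
            SimulationSpec(DEFAULT_COEFFICIENTS, ar,
                           np.linspace(0, 24, 145)[:-1], seed=seed), s)
            for s in mixed_cohort]

    def test_self_consistency(self, mixed_cohort, white_noise_ar):
        data = self._small_data(mixed_cohort, white_noise_ar)
        table = visual_predictive_check(data, DEFAULT_COEFFICIENTS, white_noise_ar,
                                        n_sim=30, seed=1)
        inside = ((table["obs_p50"] >= table["sim_p5"])
                  & (table["obs_p50"] <= table["sim_p95"]))
        assert inside.mean() >= 0.9

    def test_n_sim_too_small(self, mixed_cohort, white_noise_ar):
        data = self._small_data(mixed_cohort, white_noise_ar)
        with pytest.raises(ValueError):
            visual_predictive_check(data, DEFAULT_COEFFICIENTS, white_noise_ar,
                                    n_sim=1, seed=1)

    def test_deterministic_data_collapses_quantiles(self, noiseless_coeffs,
                                                    silent_ar, female_30):
        # one observation per hour bin, sigma = tau = 0: each bin's observed
        # and simulated percentiles collapse to the same single value
        times = np.arange(24) + 0.5
        data = [simulate_subject_rr(
            SimulationSpec(noiseless_coeffs, silent_ar, times, seed=0), female_30)]
        table = visual_predictive_check(data, noiseless_coeffs, silent_ar,
                                        n_sim=3, seed=2)
        np.testing.assert_allclose(table["sim_p5"], table["sim_p95"], rtol=1e-12)
        np.testing.assert_allclose(table["obs_p50"], table["sim_p50"], rtol=1e-12)
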