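"""Latent-variable machinery: ML CFA, factor scores, criterion statistics."""

import subprocess

import numpy as np
import pytest
from scipy import stats

from slodrsim import (SimulationConfig, correlation_with_p,
                      evaluate_slodr_criteria, fit_linear_plus_quadratic,
                      fit_one_factor, individual_log_residual_variance,
                      likelihood_ratio_test, predict_factor_scores,
                      simulate_population, skewness_test)


class TestOneFactorFit:
    def test_three_indicator_closed_form(self, rng):
        # with k = 3 the model is just-identified: the ML solution reproduces
        # the sample covariance exactly and the loadings follow the classical
        # tetrad formulas, e.g. lambda_1 = sqrt(s12 * s13 / s23)
        cfg = SimulationConfig(n_individuals=800, n_tests=3, seed=41)
        pop = simulate_population(cfg)
        fit = fit_one_factor(pop.observed_scores)
        s = fit.sample_covariance
        lam_expected = np.array([
            np.sqrt(s[0, 1] * s[0, 2] / s[1, 2]),
            np.sqrt(s[0, 1] * s[1, 2] / s[0, 2]),
            np.sqrt(s[0, 2] * s[1, 2] / s[0, 1]),
        ])
        assert np.allclose(np.abs(fit.loadings), lam_expected, atol=1e-6)
        assert np.allclose(fit.implied_covariance, s, atol=1e-6)
        assert fit.discrepancy < 1e-9

    def test_matches_r_factanal_on_standardized_metric(self):
        # independent ML implementation (base R stats::factanal) on one fixture
        cfg = SimulationConfig(n_individuals=2_000, n_tests=6,
                               disturbance_shape="none", seed=7)
        pop = simulate_population(cfg)
        fit = fit_one_factor(pop.observed_scores)
        std = fit.loadings / np.sqrt(np.diag(fit.sample_covariance))
        csv = "\n".join(",".join(f"{v:.10f}" for v in row)
                        for row in pop.observed_scores)
        script = (
            'x <- read.csv("stdin", header=FALSE);'
            'f <- factanal(x, factors=1, rotation="none");'
            'cat(as.vector(loadings(f)), sep=",")'
        )
        res = subprocess.run(["Rscript", "-e", script], input=csv,
                             capture_output=True, text=True, timeout=300)
        ref = np.array([float(v) for v in res.stdout.strip().split(",")])
        assert np.max(np.abs(np.abs(std) - np.abs(ref))) < 1e-4

    def test_loading_recovery_on_large_sample(self, big_clean_population):
        pop = big_clean_population
        fit = fit_one_factor(pop.observed_scores)
        std = fit.loadings / np.sqrt(np.diag(fit.sample_covariance))
        assert fit.converged
        assert np.max(np.abs(std - pop.loadings)) < 0.02

    def test_column_order_invariance(self, clean_population):
        x = clean_population.observed_scores[:, :6]
        perm = [3, 0, 5, 1, 4, 2]
        a = fit_one_factor(x)
        b = fit_one_factor(x[:, perm])
        assert np.allclose(np.abs(a.loadings[perm]), np.abs(b.loadings), atol=1e-5)

    def test_zero_variance_column_rejected(self, rng):
        x = rng.normal(size=(100, 4))
        x[:, 2] = 7.0
        with pytest.raises(ValueError):
            fit_one_factor(x)


class TestFactorScores:
    def test_individual_at_the_mean_scores_zero(self, clean_population):
        fit = fit_one_factor(clean_population.observed_scores)
        scores = predict_factor_scores(fit, fit.intercepts[None, :])
        assert abs(scores.g_hat[0]) < 1e-10

    def test_shrinkage_and_validity(self, big_clean_population):
        pop = big_clean_population
        fit = fit_one_factor(pop.observed_scores)
        scores = predict_factor_scores(fit, pop.observed_scores)
        var = scores.g_hat.var()
        assert var <= 1.0
        # regression-score algebra: corr(g_hat, g) ~ sqrt(lambda' Sigma^-1 lambda)
        expected = np.sqrt(fit.loadings @ np.linalg.solve(
            fit.implied_covariance, fit.loadings))
        observed = np.corrcoef(scores.g_hat, pop.true_g)[0, 1]
        assert abs(observed - expected) < 0.01

    def test_noiseless_limit_recovers_g_exactly(self, rng):
        g = rng.normal(size=400)
        x = 100 + np.outer(g, np.array([3.0, 2.0, 1.5, 1.0]))
        x += rng.normal(scale=1e-4, size=x.shape)
        fit = fit_one_factor(x)
        scores = predict_factor_scores(fit, x)
        assert abs(np.corrcoef(scores.g_hat, g)[0, 1]) > 0.999999


class TestSkewness:
    def test_symmetric_sample_has_zero_skew(self):
        x = np.concatenate([np.arange(10), -np.arange(10)])
        res = skewness_test(x)
        assert res.skew == pytest.approx(0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_third_moment(self):
        # {0, 0, 1} tiled: m2 = 2/9, m3 = 2/27, so g1 = 1/sqrt(2)
        x = np.tile([0.0, 0.0, 1.0], 3)
        assert skewness_test(x).skew == pytest.approx(1 / np.sqrt(2))

    def test_null_calibration(self, rng):
        rejections = 0
        reps, n = 1_000, 10_000
        for _ in range(reps):
            if skewness_test(rng.standard_normal(n)).p < 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) < 0.02

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            skewness_test(np.zeros(3))
        with pytest.raises(ValueError):
            skewness_test(np.full(20, 2.0))


class TestResidualVariance:
    def test_grand_mean_matches_shrinkage_corrected_thetas(self, big_clean_population):
        # residuals are taken from shrunken regression scores, so the grand
        # mean of individual residual variances equals
        # mean(theta) - (1 - rho^2) * mean(lambda^2), rho^2 = lambda' Sigma^-1 lambda
        pop = big_clean_population
        fit = fit_one_factor(pop.observed_scores)
        scores = predict_factor_scores(fit, pop.observed_scores)
        log_rv = individual_log_residual_variance(fit, pop.observed_scores,
                                                  scores.g_hat)
        grand = np.exp(log_rv).mean()
        rho2 = fit.loadings @ np.linalg.solve(fit.implied_covariance, fit.loadings)
        expected = (fit.residual_variances.mean()
                    - (1 - rho2) * np.mean(fit.loadings**2))
        assert abs(grand - expected) / expected < 0.02

    def test_floor_on_noiseless_data(self, rng):
        g = rng.normal(size=300)
        x = 100 + np.outer(g, np.array([3.0, 2.0, 1.5, 1.0]))
        x += rng.normal(scale=1e-6, size=x.shape)
        fit = fit_one_factor(x)
        scores = predict_factor_scores(fit, x)
        log_rv = individual_log_residual_variance(fit, x, scores.g_hat)
        assert np.all(np.isfinite(log_rv))
        assert np.all(log_rv >= np.log(1e-12) - 1e-9)


class TestCorrelation:
    def test_perfect_and_antiperfect(self, rng):
        a = rng.normal(size=50)
        assert correlation_with_p(a, a)[0] == pytest.approx(1.0)
        assert correlation_with_p(a, -a)[0] == pytest.approx(-1.0)

    def test_null_calibration(self, rng):
        rejections = sum(
            correlation_with_p(rng.standard_normal(1_000),
                               rng.standard_normal(1_000))[1] < 0.05
            for _ in range(1_000)
        )
        assert abs(rejections / 1_000 - 0.05) < 0.02

    def test_constant_input_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_with_p(np.ones(10), rng.normal(size=10))


class TestQuadraticModel:
    def test_hard_constraint_and_nesting(self, disturbed_population):
        x = disturbed_population.observed_scores
        lin = fit_one_factor(x)
        quad = fit_linear_plus_quadratic(x, linear_fit=lin)
        assert np.allclose(quad.loading_matrix[:, 1], quad.loadings**2)
        assert quad.discrepancy <= lin.discrepancy + 1e-9
        assert quad.loglik >= lin.loglik - 1e-6
        assert quad.quad_variance >= 0
        # implied covariance identity
        sig = (quad.loading_matrix @ quad.factor_cov @ quad.loading_matrix.T
               + np.diag(quad.residual_variances))
        assert np.allclose(sig, quad.implied_covariance)

    def test_lrt_degrees_of_freedom_and_identity_case(self, clean_population):
        x = clean_population.observed_scores
        lin = fit_one_factor(x)
        quad = fit_linear_plus_quadratic(x, linear_fit=lin)
        stat, df, p = likelihood_ratio_test(lin, quad)
        assert df == 2
        assert stat >= 0
        same = likelihood_ratio_test(lin, lin.__class__(**{
            **lin.__dict__, "n_free_params": lin.n_free_params + 2}))
        assert same[0] == pytest.approx(0.0, abs=1e-9)
        assert same[2] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_quadratic_effect_detected(self, seed):
        # an explicit g^2 term (coefficient -0.3 per squared loading) on a
        # skewed latent bends every test score; the LRT must see it.  The
        # latent is skewed so the curvature shows in the g-g^2 covariance —
        # with a symmetric latent the pure-variance component is nearly
        # absorbed by rescaled linear loadings and power is poor.
        r = np.random.default_rng(seed)
        n, k = 10_000, 15
        g = (r.chisquare(4, size=n) - 4) / np.sqrt(8)
        lam = r.uniform(0.2, 0.9, size=k)
        q = g**2 - np.mean(g**2)
        x = (100 + 15 * (np.outer(g, lam) - 0.3 * np.outer(q, lam**2)
                         + r.standard_normal((n, k)) * np.sqrt(1 - lam**2)))
        lin = fit_one_factor(x)
        quad = fit_linear_plus_quadratic(x, linear_fit=lin)
        stat, df, p = likelihood_ratio_test(lin, quad)
        assert p < 1e-4
        assert quad.quad_covariance < 0

    def test_orthogonal_restriction_is_nested(self, disturbed_population):
        x = disturbed_population.observed_scores
        lin = fit_one_factor(x)
        orth = fit_linear_plus_quadratic(x, linear_fit=lin,
                                         covariance_free=False)
        full = fit_linear_plus_quadratic(x, linear_fit=lin)
        assert orth.quad_covariance == 0.0
        assert orth.n_free_params == full.n_free_params - 1
        assert full.discrepancy <= orth.discrepancy + 1e-8 \
            <= lin.discrepancy + 1e-8


class TestCriteria:
    def test_negative_disturbance_fulfills_all(self, disturbed_population):
        res = evaluate_slodr_criteria(disturbed_population.observed_scores)
        assert res.negatively_skewed_g
        assert res.positive_res_corr
        assert res.significant_quadratic
        assert res.negative_g_g2_corr
        assert res.all_crucial

    def test_clean_data_fulfills_nothing(self, clean_population):
        res = evaluate_slodr_criteria(clean_population.observed_scores)
        assert not res.all_crucial
        assert not res.significant_quadratic

    def test_positive_disturbance_flips_skew(self):
        cfg = SimulationConfig(n_individuals=4_000,
                               disturbance_shape="positive", seed=77)
        pop = simulate_population(cfg)
        res = evaluate_slodr_criteria(pop.observed_scores)
        assert res.skew_direction == "positive"
        assert not res.negatively_skewed_g
        assert not res.all_crucial
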