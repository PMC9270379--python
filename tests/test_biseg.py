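"""Likelihood, frequentist fit, Gibbs sampler correctness (analytic
conjugate oracle, OLS consistency), priors and the stability statistic."""

import numpy as np
import pytest
from scipy import stats

from gxestab import BayesianBisegmented, BisegmentedOLS, McmcSettings, PriorSpec
from gxestab.biseg import log_likelihood, predict_mean, r_squared, stability_draws

INDEX = np.array([-6.0, -2.0, -1.0, 1.0, 3.0, 5.0])
IPB = 3.0  # mean of positive indices
TVAL = np.where(INDEX > 0, INDEX - IPB, 0.0)


def make_data(beta, sigma, seed, n_rep=4):
    rng = np.random.default_rng(seed)
    idx = np.repeat(INDEX, n_rep)
    t = np.repeat(TVAL, n_rep)
    y = predict_mean(idx, t, *beta) + rng.normal(0, sigma, idx.size)
    return y, idx, t


class TestLogLikelihood:
    def test_unit_density_point(self):
        """A single observation exactly at the mean with sigma2 = 1/(2*pi)
        has density 1, hence log-likelihood 0."""
        ll = log_likelihood([5.0], [-1.0], [0.0], (6.0, 1.0, 0.0, 1.0 / (2 * np.pi)))
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_normal_logpdf(self):
        y, idx, t = make_data((100.0, 1.2, 0.8), 3.0, seed=0)
        params = (99.0, 1.0, 0.5, 7.3)
        mean = predict_mean(idx, t, *params[:3])
        oracle = stats.norm.logpdf(y, mean, np.sqrt(params[3])).sum()
        assert log_likelihood(y, idx, t, params) == pytest.approx(oracle, rel=1e-12)

    def test_doubling_variance_at_the_mean(self):
        """With zero residuals, doubling sigma2 lowers the log-likelihood by
        log(sqrt(2)) per observation."""
        idx, t = np.repeat(INDEX, 2), np.repeat(TVAL, 2)
        beta = (50.0, 2.0, -1.0)
        y = predict_mean(idx, t, *beta)
        l1 = log_likelihood(y, idx, t, (*beta, 4.0))
        l2 = log_likelihood(y, idx, t, (*beta, 8.0))
        assert l1 - l2 == pytest.approx(y.size * np.log(np.sqrt(2.0)))

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            log_likelihood([1.0], [0.0], [0.0], (0.0, 0.0, 0.0, 0.0))


class TestFrequentistFit:
    def test_zero_noise_recovers_truth_exactly(self):
        beta = (100.0, 1.5, -0.7)
        y = predict_mean(INDEX, TVAL, *beta)
        res = BisegmentedOLS(y, INDEX, TVAL).fit()
        np.testing.assert_allclose(res.params, beta, atol=1e-8)
        assert res.mse_resid == pytest.approx(0.0, abs=1e-12)
        assert res.rsquared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        y, idx, t = make_data((90.0, 0.8, 1.1), 4.0, seed=1)
        res = BisegmentedOLS(y, idx, t).fit()
        X = np.column_stack([np.ones_like(idx), idx, t])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.params, oracle, rtol=1e-10)

    def test_interval_width_grows_with_confidence(self):
        y, idx, t = make_data((90.0, 0.8, 1.1), 4.0, seed=2)
        model = BisegmentedOLS(y, idx, t)
        widths = [
            np.diff(model.fit(confidence=c).conf_int, axis=1).ravel()
            for c in (0.80, 0.95, 0.99)
        ]
        assert (widths[0] < widths[1]).all() and (widths[1] < widths[2]).all()

    def test_rank_deficient_design_falls_back_to_single_slope(self):
        idx = np.array([-2.0, -1.0, 0.0, 3.0])  # one favorable point only
        t = np.where(idx > 0, idx - 3.0, 0.0)
        y = 10.0 + idx
        with pytest.warns(UserWarning, match="single-slope"):
            res = BisegmentedOLS(np.repeat(y, 2), np.repeat(idx, 2), np.repeat(t, 2)).fit()
        assert res.params[2] == 0.0
        assert np.isnan(res.bse[2])


class TestPriors:
    def test_minimally_informative_prior_values(self):
        prior = PriorSpec.vague()
        np.testing.assert_array_equal(prior.beta_mean, 0.0)
        np.testing.assert_array_equal(prior.beta_var, 100_000.0)
        assert prior.tau_shape == 0.001
        assert prior.tau_rate == 0.001
        # implied prior mean of tau = shape/rate = 1
        assert prior.tau_shape / prior.tau_rate == pytest.approx(1.0)

    @pytest.mark.parametrize("inflation,expected_var", [(1.0, 25.0), (10.0, 250.0)])
    def test_elicitation_moments(self, inflation, expected_var):
        prior = PriorSpec.from_frequentist(
            np.array([100.0, 1.0, 0.5]),
            np.array([5.0, 5.0, 5.0]),
            residual_ms=4.0,
            inflation=inflation,
        )
        np.testing.assert_allclose(prior.beta_mean, [100.0, 1.0, 0.5])
        np.testing.assert_allclose(prior.beta_var, expected_var)
        # precision prior mean matches 1/residual_ms regardless of inflation
        assert prior.tau_shape / prior.tau_rate == pytest.approx(0.25)

    def test_nonfinite_elicitation_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            PriorSpec.from_frequentist(
                np.array([np.nan, 0.0, 0.0]), np.ones(3), 1.0
            )


class TestGibbsSampler:
    def test_matches_analytic_conjugate_posterior(self):
        """With the precision pinned by an extremely concentrated Gamma
        prior, the Gibbs beta marginals must match the closed-form normal
        posterior of Bayesian linear regression with known noise, on 20
        random small instances (means within 3 MCSE + analytic tolerance)."""
        rng = np.random.default_rng(99)
        mcmc = McmcSettings(n_chains=2, n_iterations=4000, burn_in=500, thin=1, seed=7)
        failures = 0
        for rep in range(20):
            beta_true = rng.normal([100, 1, 0.5], [10, 0.5, 0.5])
            sigma = rng.uniform(2, 6)
            y, idx, t = make_data(beta_true, sigma, seed=rng.integers(2**31))
            tau0 = 1.0 / sigma**2
            prior_mu = rng.normal([100, 1, 0], [5, 1, 1])
            prior_var = rng.uniform(1.0, 50.0, 3)
            prior = PriorSpec(
                beta_mean=prior_mu,
                beta_var=prior_var,
                tau_shape=1e8,
                tau_rate=1e8 / tau0,
            )
            res = BayesianBisegmented(y, idx, t, prior=prior).fit(
                McmcSettings(**{**mcmc.__dict__, "seed": 7 + rep})
            )
            X = np.column_stack([np.ones_like(idx), idx, t])
            P0 = np.diag(1.0 / prior_var)
            V = np.linalg.inv(P0 + tau0 * X.T @ X)
            m = V @ (P0 @ prior_mu + tau0 * X.T @ y)
            for k, name in enumerate(("beta0", "beta1", "beta2")):
                est = res.posterior_mean(name)[0]
                mcse = res.mcse(name)[0]
                if abs(est - m[k]) > 3 * mcse + 1e-6:
                    failures += 1
        assert failures <= 3  # 3-MCSE bound: a stray miss in 60 checks is fine

    def test_posterior_matches_ols_under_vague_priors(self):
        y, idx, t = make_data((105.0, 1.3, 0.9), 3.0, seed=11, n_rep=10)
        res = BayesianBisegmented(y, idx, t).fit(
            McmcSettings(n_chains=2, n_iterations=6000, burn_in=1000, thin=1, seed=1)
        )
        ols = BisegmentedOLS(y, idx, t).fit()
        for k, name in enumerate(("beta0", "beta1", "beta2")):
            diff = abs(res.posterior_mean(name)[0] - ols.params[k])
            assert diff < 3 * res.mcse(name)[0] + 1e-3

    def test_degenerate_prior_pins_beta2(self):
        y, idx, t = make_data((100.0, 1.0, 1.0), 2.0, seed=3)
        prior = PriorSpec(
            beta_mean=np.array([0.0, 0.0, 0.7]),
            beta_var=np.array([1e5, 1e5, 1e-12]),
            tau_shape=0.001,
            tau_rate=0.001,
        )
        res = BayesianBisegmented(y, idx, t, prior=prior).fit(
            McmcSettings(n_chains=1, n_iterations=2000, burn_in=500, thin=1, seed=5)
        )
        assert res.posterior_mean("beta2")[0] == pytest.approx(0.7, abs=1e-4)

    def test_seed_determinism_bit_identical(self, quick_mcmc):
        y, idx, t = make_data((100.0, 1.0, 0.5), 3.0, seed=4)
        a = BayesianBisegmented(y, idx, t).fit(quick_mcmc).chains.draws
        b = BayesianBisegmented(y, idx, t).fit(quick_mcmc).chains.draws
        np.testing.assert_array_equal(a, b)

    def test_chain_shape_respects_protocol(self):
        y, idx, t = make_data((100.0, 1.0, 0.5), 3.0, seed=4)
        settings = McmcSettings(n_chains=3, n_iterations=1000, burn_in=100, thin=4, seed=0)
        chains = BayesianBisegmented(y, idx, t).fit(settings).chains
        assert chains.draws.shape == (1, 3, settings.n_kept, 4)
        assert settings.n_kept == 225

    def test_unidentified_hinge_warns_and_pins_beta2(self):
        idx = np.array([-2.0, -1.0, -0.5, 3.0])
        t = np.where(idx > 0, 0.0, 0.0)
        y = 10.0 + idx + np.random.default_rng(0).normal(0, 0.1, 4)
        with pytest.warns(UserWarning, match="single-slope"):
            model = BayesianBisegmented(np.tile(y, 2), np.tile(idx, 2), np.tile(t, 2))
        res = model.fit(McmcSettings(n_chains=1, n_iterations=500, burn_in=100, thin=1, seed=0))
        np.testing.assert_array_equal(res.chains.parameter("beta2"), 0.0)


class TestDerivedStatistics:
    def test_stability_subtracts_msr_over_r(self):
        """MSR = 575 with r = 3 subtracts 191.666... from every draw."""
        draws = np.array([200.0, 191.666666666666657, 100.0])
        out = stability_draws(draws, msr=575.0, r=3)
        np.testing.assert_allclose(out, draws - 575.0 / 3.0)
        assert out[1] == pytest.approx(0.0, abs=1e-12)
        assert out[2] < 0  # negative stability kept as-is

    def test_stability_with_zero_msr_is_identity(self):
        draws = np.linspace(1, 5, 7)
        np.testing.assert_array_equal(stability_draws(draws, 0.0, 3), draws)

    def test_stability_linearity_of_means(self, quick_mcmc):
        y, idx, t = make_data((100.0, 1.0, 0.5), 3.0, seed=8)
        res = BayesianBisegmented(y, idx, t).fit(quick_mcmc)
        summary = res.stability(msr=575.0, r=3)
        sigma2_mean = res.posterior_mean("sigma2")[0]
        assert summary["sigma2_di"].iloc[0] == pytest.approx(
            sigma2_mean - 575.0 / 3.0, rel=1e-12
        )

    def test_r_squared_against_direct_arithmetic(self):
        y, idx, t = make_data((100.0, 1.0, 0.5), 3.0, seed=9)
        params = (99.5, 1.1, 0.4)
        mean = predict_mean(idx, t, *params)
        oracle = 1 - ((y - mean) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r_squared(y, idx, t, params) == pytest.approx(oracle, rel=1e-12)

    def test_r_squared_edge_cases(self):
        y = predict_mean(INDEX, TVAL, 100.0, 1.0, 0.5)
        assert r_squared(y, INDEX, TVAL, (100.0, 1.0, 0.5)) == pytest.approx(1.0)
        # intercept-only fit on its own mean explains nothing
        assert r_squared(y, INDEX, TVAL, (y.mean(), 0.0, 0.0)) == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(r_squared(np.full(4, 5.0), INDEX[:4], TVAL[:4], (5.0, 0, 0)))
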