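"""Geweke diagnostic, trace summaries, DIC and cross-validation."""

import dataclasses

import numpy as np
import pytest

from gxestab import (
    AdaptabilityStabilityModel,
    BayesianBisegmented,
    BisegSimSpec,
    McmcSettings,
    PosteriorChains,
    compare_priors,
    cross_validate,
    dic,
    simulate_biseg_trial,
    total_dic,
    trace_summary,
)
from gxestab.biseg import predict_mean
from gxestab.diagnostics import DicResult, geweke, geweke_table


class TestGeweke:
    def test_linear_ramp_fails_grossly(self):
        z = geweke(np.linspace(0.0, 1.0, 2000)).z
        assert abs(z) > 10

    def test_iid_chain_passes(self):
        chain = np.random.default_rng(1).normal(size=5000)
        assert geweke(chain).passed

    def test_constant_chain_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            geweke(np.full(500, 3.0))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="100"):
            geweke(np.arange(50.0))

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            geweke(np.random.default_rng(0).normal(size=500), first=0.6, last=0.6)

    def test_autocorrelation_inflates_standard_error(self):
        """An AR(1) chain must not fail more often than iid despite its
        autocorrelation — the spectral se accounts for it."""
        rng = np.random.default_rng(2)
        fails = 0
        for _ in range(100):
            e = rng.normal(size=4000)
            x = np.empty_like(e)
            x[0] = e[0]
            for i in range(1, e.size):
                x[i] = 0.7 * x[i - 1] + e[i]
            fails += not geweke(x).passed
        assert fails <= 15

    def test_table_covers_panel(self, biseg_table, quick_mcmc):
        _, table = biseg_table
        model = AdaptabilityStabilityModel(table)
        res = model.fit(settings=quick_mcmc)
        gw = geweke_table(res.bayes.chains)
        assert len(gw) == 8 * 4 * quick_mcmc.n_chains
        assert gw["passed"].mean() > 0.8


class TestTraceSummary:
    def _chains(self, draws):
        return PosteriorChains(draws=draws, genotypes=("g",))

    def test_identical_chains_zero_spread(self):
        one = np.abs(np.random.default_rng(0).normal(size=(1, 1, 200, 4))) + 0.1
        chains = self._chains(np.repeat(one, 3, axis=1))
        ts = trace_summary(chains)
        np.testing.assert_allclose(ts.final_spread, 0.0, atol=1e-14)

    def test_single_chain_is_an_error(self):
        one = np.abs(np.random.default_rng(0).normal(size=(1, 1, 200, 4))) + 0.1
        with pytest.raises(ValueError, match="2 chains"):
            trace_summary(self._chains(one))

    def test_running_mean_is_cumulative_average(self):
        draws = np.abs(np.random.default_rng(3).normal(size=(1, 2, 50, 4))) + 0.1
        ts = trace_summary(self._chains(draws))
        np.testing.assert_allclose(
            ts.running_means[0, 0, -1], draws[0, 0].mean(axis=0), rtol=1e-12
        )

    def test_longer_chains_shrink_between_chain_spread(self):
        """The visual-convergence contrast: short runs disagree across
        chains far more than long runs on the same posterior."""
        y_idx = np.array([-6.0, -2.0, -1.0, 1.0, 3.0, 5.0])
        t = np.where(y_idx > 0, y_idx - 3.0, 0.0)
        rng = np.random.default_rng(8)
        y = predict_mean(np.repeat(y_idx, 3), np.repeat(t, 3), 100.0, 1.0, 0.5)
        y = y + rng.normal(0, 8.0, y.size)
        model = BayesianBisegmented(y, np.repeat(y_idx, 3), np.repeat(t, 3))
        short = model.fit(McmcSettings(n_chains=4, n_iterations=150, burn_in=50, thin=1, seed=2))
        long = model.fit(McmcSettings(n_chains=4, n_iterations=8000, burn_in=50, thin=1, seed=2))
        s_spread = trace_summary(short.chains).final_spread[0, 0]
        l_spread = trace_summary(long.chains).final_spread[0, 0]
        assert l_spread < s_spread


class TestDic:
    def test_field_identity(self, biseg_table, quick_mcmc):
        _, table = biseg_table
        res = AdaptabilityStabilityModel(table).fit(settings=quick_mcmc)
        d = total_dic(res.bayes)
        assert d.dic == pytest.approx(d.d_bar + d.p_d, rel=1e-8)
        assert d.dic == pytest.approx(d.d_hat + 2 * d.p_d, rel=1e-8)
        assert np.isfinite(d.p_d)

    def test_point_mass_posterior_has_zero_pd(self):
        idx = np.array([-2.0, -1.0, 1.0, 2.0])
        t = np.where(idx > 0, idx - 1.5, 0.0)
        y = predict_mean(idx, t, 10.0, 1.0, 0.5) + np.array([0.1, -0.1, 0.1, -0.1])
        draws = np.tile(np.array([10.0, 1.0, 0.5, 2.0]), (1, 2, 100, 1))
        chains = PosteriorChains(draws=draws, genotypes=("g",))
        d = dic(chains, y, idx, t)
        assert d.p_d == pytest.approx(0.0, abs=1e-10)
        assert d.dic == pytest.approx(d.d_hat, abs=1e-9)

    def test_bisegmented_beats_single_slope_on_hinged_data(self):
        """When the truth has a strong slope change, the hinge model's DIC
        is lower than the single-slope model's in >= 9 of 10 replicates."""
        idx = np.repeat(np.array([-6.0, -2.0, -1.0, 1.0, 3.0, 5.0]), 3)
        t = np.repeat(np.where(
            np.array([-6.0, -2.0, -1.0, 1.0, 3.0, 5.0]) > 0,
            np.array([-6.0, -2.0, -1.0, 1.0, 3.0, 5.0]) - 3.0, 0.0), 3)
        settings = McmcSettings(n_chains=1, n_iterations=2500, burn_in=500, thin=1, seed=0)
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(600 + rep)
            y = predict_mean(idx, t, 100.0, 1.0, 4.0) + rng.normal(0, 2.0, idx.size)
            s = dataclasses.replace(settings, seed=rep)
            hinge = BayesianBisegmented(y, idx, t).fit(s)
            flat = BayesianBisegmented(y, idx, np.zeros_like(t)).fit(s)
            d_h = dic(hinge.chains, y, idx, t)
            d_f = dic(flat.chains, y, idx, np.zeros_like(t))
            wins += d_h.dic < d_f.dic
        assert wins >= 9


class TestComparePriors:
    def test_within_threshold_keeps_vaguer(self):
        comp = compare_priors({"vague": 101.5, "elicited": 100.0})
        assert comp.no_increment
        assert comp.selected == "vague"

    def test_clear_winner_selected(self):
        comp = compare_priors({"vague": 100.0, "elicited": 95.0})
        assert not comp.no_increment
        assert comp.selected == "elicited"

    def test_single_model_trivial(self):
        comp = compare_priors({"only": DicResult(10.0, 8.0, 2.0, 12.0)})
        assert comp.selected == "only"


class TestCrossValidation:
    def test_fold_partition_contract(self, biseg_table):
        """Folds are disjoint, their union is the full table, and every
        genotype appears in every training set."""
        from gxestab.diagnostics import fold_assignments

        _, table = biseg_table
        Y, _ = table.observation_matrix()
        g, n = Y.shape
        fold_of = fold_assignments(g, n, 10, seed=0)
        for i in range(g):
            counts = np.bincount(fold_of[i], minlength=10)
            assert counts.sum() == n                # union is everything
            assert counts.max() - counts.min() <= 1  # balanced round-robin
            assert (n - counts >= 1).all()           # present in all training sets

    def test_noiseless_data_predicts_perfectly(self):
        spec = BisegSimSpec(
            betas=np.column_stack(
                [np.linspace(80, 120, 12), np.linspace(0.5, 1.5, 12), np.linspace(-1, 1, 12)]
            ),
            index=np.array([-9.0, -3.0, 4.0, 8.0]),
            sigma=0.0,
            seed=0,
        )
        table = simulate_biseg_trial(spec)
        model = AdaptabilityStabilityModel(table)
        design = model.environmental_index()
        cv = cross_validate(
            table,
            design,
            settings=McmcSettings(n_chains=1, n_iterations=600, burn_in=100, thin=1, seed=1),
            n_folds=10,
            seed=2,
        )
        assert cv.mean_correlation > 0.999

    def test_determinism_under_fixed_seed(self, biseg_table):
        _, table = biseg_table
        design = AdaptabilityStabilityModel(table).environmental_index()
        settings = McmcSettings(n_chains=1, n_iterations=400, burn_in=100, thin=1, seed=3)
        a = cross_validate(table, design, settings=settings, n_folds=5, seed=4)
        b = cross_validate(table, design, settings=settings, n_folds=5, seed=4)
        np.testing.assert_array_equal(a.fold_correlations, b.fold_correlations)
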