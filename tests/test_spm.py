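"""Surplus-production model: projection, likelihood, fitting, summaries."""

import numpy as np
import pandas as pd
import pytest

import reefcatch as rc
from reefcatch.errors import DataError, DomainError
from reefcatch.spm import (
    CPUESeries,
    MCMCConfig,
    SPMParameters,
    SPMPosterior,
    expected_cpue,
    fit_r_squared,
    log_likelihood,
    project_biomass,
)
from reefcatch.synthetic import SPMSimConfig


def _params(**kw):
    base = dict(r=0.3, K=5000.0, q_pre=0.001, q_post=0.001, sigma_obs=0.1,
                psi=1.0)
    base.update(kw)
    return SPMParameters(**base)


def _series(catch, cpue, first_year=2000, regime_year=None):
    n = len(catch)
    return CPUESeries("s", np.arange(first_year, first_year + n),
                      np.asarray(catch, float), np.asarray(cpue, float),
                      regime_year)


class TestProjectBiomass:
    def test_msy_equilibrium_is_exact_for_random_parameters(self, rng):
        """Catching rK/4 from B=K/2 leaves biomass identically at K/2."""
        for _ in range(100):
            p = _params(r=rng.uniform(0.05, 0.9), K=rng.uniform(100, 1e5),
                        psi=0.5)
            catch = np.full(30, p.r * p.K / 4.0)
            B, hit = project_biomass(p, catch, 30)
            assert not hit
            assert np.all(B == p.K * 0.5)

    def test_carrying_capacity_is_a_fixed_point(self, rng):
        for _ in range(100):
            p = _params(r=rng.uniform(0.05, 0.9), K=rng.uniform(100, 1e5),
                        psi=1.0)
            B, hit = project_biomass(p, np.zeros(30), 30)
            assert not hit
            assert np.all(B == p.K)

    def test_hand_computed_recursion(self):
        p = _params(r=0.2, K=1000.0, psi=1.0)
        B, hit = project_biomass(p, np.array([50.0, 50.0]), 3)
        assert not hit
        assert B == pytest.approx([1000.0, 950.0, 909.5])

    def test_matches_independent_recursion_on_random_instances(self, rng):
        """Oracle equivalence on 1000 random parameter/catch draws."""
        for _ in range(1000):
            r = rng.uniform(0.02, 1.0)
            K = rng.uniform(10, 1e6)
            psi = rng.uniform(0.2, 1.0)
            n = int(rng.integers(2, 30))
            catch = rng.uniform(0, 0.3 * K, size=n)
            B, _ = project_biomass(_params(r=r, K=K, psi=psi), catch, n)
            b = psi * K
            for t in range(n):
                assert B[t] == pytest.approx(b, rel=1e-12)
                nxt = b + r * b * (1.0 - b / K) - catch[t]
                b = max(nxt, 1e-6 * K)

    def test_floor_hit_is_flagged(self):
        p = _params(r=0.1, K=100.0)
        B, hit = project_biomass(p, np.array([500.0, 0.0]), 3)
        assert hit
        assert B[1] == pytest.approx(1e-4)


class TestExpectedCpue:
    def test_proportional_to_biomass(self):
        p = _params(q_pre=0.001)
        years = np.arange(2000, 2004)
        out = expected_cpue(p, np.full(4, 1000.0), years)
        assert np.allclose(out, 1.0)

    def test_efficiency_trend_is_geometric(self):
        p = _params(q_pre=0.001)
        years = np.arange(2000, 2010)
        out = expected_cpue(p, np.full(10, 1000.0), years,
                            efficiency_trend_pct=1.0)
        assert np.allclose(out[1:] / out[:-1], 1.01)

    def test_regime_year_switches_catchability(self):
        p = _params(q_pre=1.0, q_post=2.0)
        years = np.arange(2000, 2004)
        out = expected_cpue(p, np.full(4, 1.0), years, regime_year=2002)
        assert np.allclose(out, [1, 1, 2, 2])


class TestLogLikelihood:
    def test_doubling_sigma_at_exact_fit_costs_n_log_2(self):
        p = _params(sigma_obs=0.2, psi=1.0)
        B, _ = project_biomass(p, np.zeros(10), 10)
        cpue = p.q_pre * B
        s = _series(np.zeros(10), cpue)
        ll1 = log_likelihood(p, s)
        ll2 = log_likelihood(_params(sigma_obs=0.4, psi=1.0), s)
        assert ll1 - ll2 == pytest.approx(10 * np.log(2))

    def test_floor_hit_gives_minus_inf(self):
        p = _params(r=0.1, K=100.0)
        s = _series([500.0, 0.0, 0.0], [0.1, 0.1, 0.1])
        assert log_likelihood(p, s) == -np.inf

    def test_gap_years_contribute_nothing(self):
        p = _params(psi=1.0)
        B, _ = project_biomass(p, np.zeros(6), 6)
        cpue = p.q_pre * B
        full = _series(np.zeros(6), cpue)
        gappy_cpue = cpue.copy()
        gappy_cpue[2] = np.nan
        gappy = _series(np.zeros(6), gappy_cpue)
        expected_drop = (
            -np.log(p.sigma_obs) - 0.5 * np.log(2 * np.pi) - np.log(cpue[2])
        )
        assert log_likelihood(p, full) - log_likelihood(p, gappy) == \
            pytest.approx(expected_drop)

    def test_unit_relabelling_shifts_likelihood_by_jacobian_only(self):
        """Scaling CPUE and q jointly by c changes the log likelihood by
        exactly -n log c (the change of variable), leaving the (r, K)
        profile shape untouched."""
        p = _params(sigma_obs=0.15)
        sim = rc.simulate_spm_series(SPMSimConfig(seed=4))
        s = sim.series
        c = 37.0
        scaled = _series(s.catch, s.cpue * c, first_year=s.years[0])
        p_scaled = _params(sigma_obs=0.15, q_pre=p.q_pre * c,
                           q_post=p.q_post * c)
        n = len(s.years)
        assert log_likelihood(p_scaled, scaled) == pytest.approx(
            log_likelihood(p, s) - n * np.log(c)
        )


class TestFitSpm:
    def test_posterior_medians_recover_truth(self, recovered_stock):
        sim, post = recovered_stock
        med = post.draws[["r", "K"]].median()
        assert abs(med["r"] - sim.truth["r"]) / sim.truth["r"] <= 0.3
        assert abs(med["K"] - sim.truth["K"]) / sim.truth["K"] <= 0.3

    def test_msy_identity_on_stored_draws(self, recovered_stock):
        _, post = recovered_stock
        d = post.draws
        assert np.array_equal(d["msy"], d["r"] * d["K"] / 4.0)

    def test_diagnostics_pass_the_gate(self, recovered_stock):
        _, post = recovered_stock
        assert max(post.diagnostics["rhat"].values()) < 1.05
        assert min(post.diagnostics["ess"].values()) >= 400

    def test_fit_r_squared_above_0_8_on_low_noise_series(self, recovered_stock):
        _, post = recovered_stock
        assert fit_r_squared(post) > 0.8

    def test_all_gap_cpue_is_a_data_error(self):
        s = _series(np.full(12, 10.0), np.full(12, np.nan))
        with pytest.raises(DataError):
            rc.fit_spm(s)

    def test_short_series_warns(self):
        sim = rc.simulate_spm_series(SPMSimConfig(seed=2, n_years=8))
        loose = MCMCConfig(warmup=300, draws=300, rhat_max=10.0, ess_min=1.0,
                           max_doublings=0, seed=0)
        with pytest.warns(UserWarning, match="observed CPUE years"):
            rc.fit_spm(sim.series, mcmc=loose)

    def test_efficiency_trend_sensitivity(self):
        """Fitting a trend-generated series with the trend enabled
        recovers r; ignoring the trend reads rising efficiency as stock
        recovery and inflates estimated depletion."""
        sim = rc.simulate_spm_series(
            SPMSimConfig(seed=5, efficiency_trend_pct=1.0)
        )
        on = rc.fit_spm(sim.series, mcmc=MCMCConfig(seed=5),
                        efficiency_trend_pct=1.0)
        off = rc.fit_spm(sim.series, mcmc=MCMCConfig(seed=5),
                         efficiency_trend_pct=0.0)
        r_on = on.draws["r"].median()
        assert abs(r_on - 0.3) / 0.3 <= 0.3
        assert off.draws["depletion"].median() > on.draws["depletion"].median()

    def test_prior_predictive_cpue_is_positive_and_finite(self, rng):
        """Parameters sampled from the priors simulate to positive finite
        CPUE in at least 99% of draws."""
        priors = rc.SPMPriors(K_mu=float(np.log(5 * 400.0)))
        sim = rc.simulate_spm_series(SPMSimConfig(seed=4))
        catch = sim.series.catch
        years = sim.series.years
        good = 0
        n_draws = 500
        for _ in range(n_draws):
            p = SPMParameters(
                r=float(np.exp(rng.normal(priors.r_mu, priors.r_sd))),
                K=float(np.exp(rng.normal(priors.K_mu, priors.K_sd))),
                q_pre=float(np.exp(rng.normal(-7, 2))),
                q_post=float(np.exp(rng.normal(-7, 2))),
                sigma_obs=float(abs(rng.normal(0, priors.sigma_scale))),
                psi=float(rng.uniform(0.2, 1.0)),
            )
            B, _ = project_biomass(p, catch, len(years))
            cpue = expected_cpue(p, B, years)
            good += bool(np.all(np.isfinite(cpue)) and np.all(cpue > 0))
        assert good / n_draws >= 0.99


class TestSummaries:
    def _degenerate_posterior(self, depletion=0.5):
        draws = pd.DataFrame(
            {"chain": [0], "draw": [0], "r": [0.3], "K": [5000.0],
             "q_pre": [1e-3], "q_post": [1e-3], "sigma_obs": [0.05],
             "psi": [1.0], "msy": [375.0], "depletion": [depletion]}
        )
        s = _series(np.zeros(5), np.full(5, 5.0))
        return SPMPosterior("d", draws, {}, s)

    def test_single_draw_depletion_summary(self):
        assert rc.depletion_summary(self._degenerate_posterior()) == (
            50.0, 50.0, 50.0
        )

    def test_two_point_depletion_median(self):
        post = self._degenerate_posterior()
        post.draws = pd.concat(
            [post.draws.assign(depletion=0.4), post.draws.assign(depletion=0.6)]
        )
        _, med, _ = rc.depletion_summary(post)
        assert med == pytest.approx(50.0)

    def test_r_squared_is_one_for_exact_posterior(self):
        p = _params(sigma_obs=0.05, psi=1.0, r=0.3, K=5000.0)
        B, _ = project_biomass(p, np.full(10, 100.0), 10)
        s = _series(np.full(10, 100.0), p.q_pre * B)
        draws = pd.DataFrame(
            {"r": [p.r], "K": [p.K], "q_pre": [p.q_pre], "q_post": [p.q_post],
             "sigma_obs": [p.sigma_obs], "psi": [p.psi]}
        )
        post = SPMPosterior("d", draws, {}, s)
        assert fit_r_squared(post) == pytest.approx(1.0)

    def test_r_squared_is_zero_for_constant_prediction(self):
        p = _params(psi=1.0)
        s = _series(np.zeros(6), np.array([1.0, 1.2, 0.9, 1.1, 1.05, 0.95]))
        draws = pd.DataFrame(
            {"r": [p.r], "K": [p.K], "q_pre": [p.q_pre], "q_post": [p.q_post],
             "sigma_obs": [p.sigma_obs], "psi": [p.psi]}
        )
        post = SPMPosterior("d", draws, {}, s)
        assert fit_r_squared(post) == 0.0

    def test_r_squared_needs_three_observations(self):
        s = _series([0.0, 0.0, 0.0], [1.0, np.nan, np.nan])
        post = self._degenerate_posterior()
        with pytest.raises(DataError):
            fit_r_squared(post, s)


class TestCpueSeriesValidation:
    def test_years_must_be_consecutive(self):
        with pytest.raises(DomainError):
            CPUESeries("x", [2000, 2002], [1.0, 1.0], [1.0, 1.0])

    def test_observed_cpue_must_be_positive(self):
        with pytest.raises(DomainError):
            CPUESeries("x", [2000, 2001], [1.0, 1.0], [0.0, 1.0])

    def test_catch_must_be_complete(self):
        with pytest.raises(DomainError):
            CPUESeries("x", [2000, 2001], [np.nan, 1.0], [1.0, 1.0])
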