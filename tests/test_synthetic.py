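"""Synthetic-data generators: ground truth, reproducibility, dynamics."""

import numpy as np
import pandas as pd
import pytest

import reefcatch as rc
from reefcatch.errors import ConfigurationError, DomainError, SimulationError
from reefcatch.habitat import classify_species_table
from reefcatch.regression import RegressionMCMC
from reefcatch.synthetic import SPMSimConfig, SimConfig


class TestHabitatGenerator:
    def test_all_category_1_means_no_coral_flags(self):
        h = rc.generate_habitat_database(
            SimConfig(n_species=20, category_probs=(1, 0, 0, 0), seed=0)
        )
        assert not h.evidence["coral_assoc"].any()

    def test_all_category_4_means_every_species_has_obligate_row(self):
        h = rc.generate_habitat_database(
            SimConfig(n_species=20, category_probs=(0, 0, 0, 1), seed=0)
        )
        per_species = h.evidence.groupby("species_id")["live_coral_obligate"].any()
        assert per_species.all() and len(per_species) == 20

    def test_classifier_recovers_ground_truth_exactly(self):
        h = rc.generate_habitat_database(SimConfig(seed=7))
        got = classify_species_table(h.evidence)
        truth = dict(zip(h.truth.species_id, h.truth.true_category))
        assert {s: int(c) for s, c in got.items()} == truth

    def test_every_species_has_at_least_one_row(self):
        h = rc.generate_habitat_database(SimConfig(seed=3))
        assert h.evidence["species_id"].nunique() == 57

    def test_flag_hierarchy_holds_on_every_row(self):
        h = rc.generate_habitat_database(SimConfig(seed=11))
        e = h.evidence
        assert (~e.live_coral_obligate | e.live_coral_dependent).all()
        assert (~e.live_coral_dependent | e.coral_assoc).all()
        assert ((e.substrate != "coral_reef") | e.coral_assoc).all()

    def test_bit_reproducible_for_fixed_seed(self):
        a = rc.generate_habitat_database(SimConfig(seed=9))
        b = rc.generate_habitat_database(SimConfig(seed=9))
        pd.testing.assert_frame_equal(a.evidence, b.evidence)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(category_probs=(0.5, 0.5, 0.5, 0.5))


class TestCatchGenerator:
    def test_zero_slope_zero_noise_gives_identical_shares(self):
        cfg = SimConfig(seed=3, reef_effect_slope=0.0, catch_noise_cv=0.0)
        tables = rc.generate_catch_tables(cfg, np.linspace(0, 20, 9))
        catalog = dict(zip(tables.truth.taxon_label, tables.truth.true_category))
        profiles = rc.aggregate_profile(tables.catch, catalog, "region",
                                        (2008, 2017))
        for p in profiles:
            assert np.allclose(p.shares, [50, 30, 15, 5])

    def test_noiseless_slope_is_exactly_linear_in_reef_area(self):
        cfg = SimConfig(seed=0, reef_effect_slope=2.0, catch_noise_cv=0.0,
                        n_regions=2)
        tables = rc.generate_catch_tables(cfg, np.array([0.0, 10.0]))
        catalog = dict(zip(tables.truth.taxon_label, tables.truth.true_category))
        profiles = {
            p.key: p
            for p in rc.aggregate_profile(tables.catch, catalog, "region",
                                          (2008, 2017))
        }
        reef = dict(zip(tables.regions.region, tables.regions.reef_pct))
        shares = sorted((reef[k], p.share(3)) for k, p in profiles.items())
        assert shares[1][1] - shares[0][1] == pytest.approx(20.0)

    def test_negative_reef_percentage_rejected(self):
        with pytest.raises(DomainError):
            rc.generate_catch_tables(SimConfig(n_regions=2),
                                     np.array([-1.0, 5.0]))

    def test_regression_recovers_built_in_slope(self):
        """Downstream regression credible intervals cover the generator's
        slope in at least 90% of 50 seeded replicates."""
        reef = np.linspace(0, 20, 9)
        covered = 0
        for seed in range(50):
            cfg = SimConfig(seed=seed, reef_effect_slope=2.0,
                            catch_noise_cv=0.1)
            tables = rc.generate_catch_tables(cfg, reef)
            catalog = dict(
                zip(tables.truth.taxon_label, tables.truth.true_category)
            )
            profiles = rc.aggregate_profile(tables.catch, catalog, "region",
                                            (2008, 2017))
            reefmap = dict(zip(tables.regions.region, tables.regions.reef_pct))
            data = rc.RegressionData(
                x=np.array([reefmap[p.key] for p in profiles]),
                y=np.array([p.share(3) for p in profiles]),
                category=3,
            )
            post = rc.fit_linear_model(
                data, mcmc=RegressionMCMC(warmup=500, draws=1000, seed=seed)
            )
            lo, hi = post.ci95
            covered += lo <= 2.0 <= hi
        assert covered >= 45


class TestSPMSimulation:
    def test_msy_equilibrium_holds_cpue_constant(self):
        cfg = SPMSimConfig(r_true=0.3, K_true=5000, sigma_obs=0.0,
                           harvest_pattern="constant_fraction",
                           initial_depletion=0.5, seed=0)
        sim = rc.simulate_spm_series(cfg)
        assert np.allclose(sim.series.catch, 0.3 * 5000 / 4)
        assert np.allclose(sim.series.cpue, cfg.q_pre * 5000 / 2)

    def test_unfished_stock_stays_at_carrying_capacity(self):
        cfg = SPMSimConfig(sigma_obs=0.0, catch_series=np.zeros(40), seed=0)
        sim = rc.simulate_spm_series(cfg)
        assert np.allclose(sim.biomass, cfg.K_true)

    def test_matches_independent_recursion_exactly(self, rng):
        """Forward simulation with no noise equals a separately coded
        logistic-with-harvest recursion, bit for bit."""
        for _ in range(50):
            r = rng.uniform(0.05, 0.6)
            K = rng.uniform(500, 20000)
            catch = rng.uniform(0, 0.02 * K, size=25)
            cfg = SPMSimConfig(r_true=r, K_true=K, sigma_obs=0.0,
                               catch_series=catch, n_years=25, seed=0)
            sim = rc.simulate_spm_series(cfg)
            b = K
            for t in range(25):
                assert sim.biomass[t] == b
                b = b + r * b * (1 - b / K) - catch[t]

    def test_overharvest_rejected_with_year_named(self):
        catch = np.full(10, 2000.0)  # far above MSY of r K/4 = 375
        cfg = SPMSimConfig(catch_series=catch, n_years=10, first_year=2000,
                           seed=0)
        with pytest.raises(SimulationError, match=r"year 20\d\d"):
            rc.simulate_spm_series(cfg)

    def test_regime_change_scales_cpue(self):
        cfg = SPMSimConfig(sigma_obs=0.0, q_pre=0.001, q_post=0.002,
                           regime_year=2004, catch_series=np.zeros(40), seed=0)
        sim = rc.simulate_spm_series(cfg)
        pre = sim.series.cpue[sim.series.years < 2004]
        post = sim.series.cpue[sim.series.years >= 2004]
        assert np.allclose(post, 2 * pre[0])
        assert np.allclose(pre, pre[0])

    def test_bit_reproducible_for_fixed_seed(self):
        a = rc.simulate_spm_series(SPMSimConfig(seed=42))
        b = rc.simulate_spm_series(SPMSimConfig(seed=42))
        assert np.array_equal(a.series.cpue, b.series.cpue)
        assert np.array_equal(a.biomass, b.biomass)
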