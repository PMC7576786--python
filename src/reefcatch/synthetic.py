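"""Synthetic input tables with known ground truth.

Every downstream stage is testable without any portal download: this
module fabricates (a) a habitat-evidence table whose boolean coral flags
encode a known per-species dependence category, (b) regional catch
tables in which the percent of catch in the live-coral-dependent
category rises linearly with a region's percent reef area, (c) the
region table itself, and (d) catch+CPUE series generated by the forward
Schaefer model with a catchability regime change. Defaults mirror the
study conditions: 57 commercially fished taxa, the nine Queensland
reporting regions, the 2008-2017 analysis decade, and 40-year CPUE
series ending in 2018.

All randomness derives from a single master seed per generator call
(sub-streams are spawned deterministically), so outputs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, SimulationError
from .habitat import LifeStage, ObservationMethod, Substrate
from .spm import CPUESeries

__all__ = [
    "SimConfig",
    "SPMSimConfig",
    "SyntheticHabitat",
    "SyntheticCatch",
    "SimulatedStock",
    "generate_habitat_database",
    "generate_catch_tables",
    "simulate_spm_series",
    "QUEENSLAND_REGIONS",
]

#: the nine commercial reporting ("Mapstone") regions, north to south
QUEENSLAND_REGIONS = (
    "eastern_torres_strait",
    "gulf_of_carpentaria",
    "far_northern",
    "cairns",
    "townsville",
    "mackay",
    "swains",
    "capricorn_bunker",
    "sub_tropical",
)

_GEARS = ("line", "pot", "net", "otter_trawl", "dive", "beam_trawl")


@dataclass
class SimConfig:
    """Conditions for the habitat/catch generators.

    category_probs is the species-level prevalence of the four
    dependence categories; reef_effect_slope is the built-in linear
    effect (percentage points of category-3 catch share per percentage
    point of reef area); catch_noise_cv is the lognormal CV applied per
    taxon-region cell.
    """

    n_species: int = 57
    n_regions: int = 9
    n_years: int = 10
    first_year: int = 2008
    category_probs: tuple[float, float, float, float] = (0.50, 0.30, 0.15, 0.05)
    reef_effect_slope: float = 2.0
    catch_noise_cv: float = 0.1
    region_total_catch: float = 1000.0  # tonnes/yr per region
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.category_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0):
            raise ConfigurationError("category_probs must be 4 non-negative values")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("category_probs must sum to 1 (tol 1e-9)")
        if self.n_years < 2:
            raise ConfigurationError("n_years must be >= 2")
        if min(self.n_species, self.n_regions) < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.catch_noise_cv < 0:
            raise ConfigurationError("catch_noise_cv must be >= 0")


class SyntheticHabitat(NamedTuple):
    evidence: pd.DataFrame   # habitat-evidence schema
    truth: pd.DataFrame      # species_id, true_category (sidecar, never merged)


class SyntheticCatch(NamedTuple):
    catch: pd.DataFrame      # catch schema
    regions: pd.DataFrame    # region, reef_pct
    truth: pd.DataFrame      # taxon_label, true_category sidecar


def _species_ids(config: SimConfig) -> list[str]:
    return [f"sp{i:03d}" for i in range(config.n_species)]


def _species_categories(config: SimConfig) -> np.ndarray:
    """Ground-truth category per species, shared across generators.

    Uses its own deterministic sub-stream of the master seed so the
    habitat and catch generators agree on every species' category.
    """
    rng = np.random.default_rng([config.seed, 101])
    return rng.choice(np.arange(1, 5), size=config.n_species, p=config.category_probs)


_NONREEF_SUBSTRATES = (
    Substrate.UNVEGETATED_SOFT,
    Substrate.SEAGRASS,
    Substrate.MANGROVE,
    Substrate.ROCKY_REEF,
)


def generate_habitat_database(config: SimConfig) -> SyntheticHabitat:
    """Evidence rows whose flag hierarchy encodes each species' category.

    Each species gets one defining row at its category level plus 0-2
    lower-evidence rows (which never change the classification, since
    the classifier takes the maximum over rows), so re-classifying the
    table recovers the ground truth exactly by construction.
    """
    cats = _species_categories(config)
    rng = np.random.default_rng([config.seed, 102])
    rows = []

    stages = (LifeStage.JUVENILE.value, LifeStage.ADULT.value,
              LifeStage.UNSPECIFIED.value)
    methods = tuple(m.value for m in ObservationMethod)

    def _row(sp, substrate, assoc, dep, obl):
        rows.append(
            {
                "species_id": sp,
                "life_stage": stages[rng.integers(len(stages))],
                "method": methods[rng.integers(len(methods))],
                "habitat_kind": "substrate",
                "substrate": substrate.value,
                "coral_assoc": bool(assoc),
                "live_coral_dependent": bool(dep),
                "live_coral_obligate": bool(obl),
                "source_ref": f"synthetic:{sp}",
            }
        )

    for sp, cat in zip(_species_ids(config), cats):
        if cat == 1:
            _row(sp, _NONREEF_SUBSTRATES[rng.integers(len(_NONREEF_SUBSTRATES))], False, False, False)
        elif cat == 2:
            _row(sp, Substrate.CORAL_REEF, True, False, False)
        elif cat == 3:
            _row(sp, Substrate.CORAL_REEF, True, True, False)
        else:
            _row(sp, Substrate.CORAL_REEF, True, True, True)
        # optional corroborating lower-level rows
        for _ in range(rng.integers(0, 3)):
            if cat == 1:
                _row(sp, _NONREEF_SUBSTRATES[rng.integers(len(_NONREEF_SUBSTRATES))], False, False, False)
            else:
                _row(sp, Substrate.CORAL_REEF, True, False, False)

    evidence = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {"species_id": _species_ids(config), "true_category": cats.astype(int)}
    )
    return SyntheticHabitat(evidence=evidence, truth=truth)


def generate_catch_tables(
    config: SimConfig, region_reef_pct: np.ndarray
) -> SyntheticCatch:
    """Catch and region tables embedding a linear reef-area effect.

    The expected percent of category-3 catch in region i is
    ``baseline + reef_effect_slope * reef_pct_i`` (clipped to [0, 100]),
    where the baseline is the configured category-3 prevalence in
    percent; the remaining share is split among categories 1, 2 and 4 in
    proportion to their prevalences. Within a category the share is
    divided equally among that category's taxa, and each taxon-region
    cell receives a single multiplicative lognormal noise factor with
    the configured CV (mean 1), constant across years.
    """
    reef = np.asarray(region_reef_pct, dtype=float)
    if len(reef) != config.n_regions:
        raise DomainError(
            f"region_reef_pct must have {config.n_regions} entries, got {len(reef)}"
        )
    if np.any(reef < 0) or np.any(reef > 100):
        raise DomainError("reef percentages must lie in [0, 100]")

    cats = _species_categories(config)
    species = np.array(_species_ids(config))
    probs = np.asarray(config.category_probs, dtype=float)
    rng = np.random.default_rng([config.seed, 103])

    regions = [
        QUEENSLAND_REGIONS[i] if i < len(QUEENSLAND_REGIONS) else f"region{i:02d}"
        for i in range(config.n_regions)
    ]
    gear_of = {sp: _GEARS[i % len(_GEARS)] for i, sp in enumerate(species)}

    baseline3 = probs[2] * 100.0
    other = np.array([probs[0], probs[1], probs[3]])
    other = other / other.sum() if other.sum() > 0 else other

    cv = config.catch_noise_cv
    if cv > 0:
        s2 = np.log1p(cv**2)
        noise = rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2),
                              size=(config.n_regions, config.n_species))
    else:
        noise = np.ones((config.n_regions, config.n_species))

    years = np.arange(config.first_year, config.first_year + config.n_years)
    rows = []
    for i, region in enumerate(regions):
        p3 = float(np.clip(baseline3 + config.reef_effect_slope * reef[i], 0, 100))
        pct = np.empty(4)
        pct[2] = p3
        pct[[0, 1, 3]] = (100.0 - p3) * other
        for c in range(1, 5):
            members = species[cats == c]
            if members.size == 0 or pct[c - 1] <= 0:
                continue
            base = config.region_total_catch * pct[c - 1] / 100.0 / members.size
            for sp in members:
                j = int(np.nonzero(species == sp)[0][0])
                qty = base * noise[i, j]
                for year in years:
                    rows.append(
                        {
                            "taxon_label": sp,
                            "region": region,
                            "sector": gear_of[sp],
                            "year": int(year),
                            "quantity": qty,
                            "basis": "weight_tonnes",
                        }
                    )

    catch = pd.DataFrame(rows)
    region_table = pd.DataFrame({"region": regions, "reef_pct": reef})
    truth = pd.DataFrame({"taxon_label": species, "true_category": cats.astype(int)})
    return SyntheticCatch(catch=catch, regions=region_table, truth=truth)


# ---------------------------------------------------------------------------
# forward surplus-production simulation


@dataclass
class SPMSimConfig:
    """True parameter values for a forward Schaefer simulation.

    harvest_pattern shapes the exploitation history: "up_down" (effort
    rises then falls — the default, because one-way histories leave r
    and K weakly identified), "one_way" (monotone rise) or
    "constant_fraction" (harvest rate r/2, which holds a stock started
    at half-depletion exactly at MSY equilibrium). An explicit
    ``catch_series`` overrides the pattern. ``process_error_sd`` adds
    lognormal process noise to the biomass update (off by default, for
    robustness probing only).
    """

    r_true: float = 0.3
    K_true: float = 5000.0
    q_pre: float = 0.001
    q_post: float = 0.001
    sigma_obs: float = 0.05
    regime_year: int | None = None
    harvest_pattern: str = "up_down"
    n_years: int = 40
    first_year: int = 1979
    initial_depletion: float = 1.0
    efficiency_trend_pct: float = 0.0
    process_error_sd: float = 0.0
    catch_series: np.ndarray | None = None
    stock_id: str = "synthetic_stock"
    seed: int = 0

    def __post_init__(self):
        for name in ("r_true", "K_true", "q_pre", "q_post", "initial_depletion"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.sigma_obs < 0 or self.process_error_sd < 0:
            raise ConfigurationError("noise sds must be non-negative")
        if self.initial_depletion > 1:
            raise ConfigurationError("initial_depletion cannot exceed 1")
        if self.n_years < 2:
            raise ConfigurationError("n_years must be >= 2")
        if self.harvest_pattern not in ("one_way", "up_down", "constant_fraction"):
            raise ConfigurationError(
                f"unknown harvest pattern {self.harvest_pattern!r}"
            )
        last = self.first_year + self.n_years - 1
        if self.regime_year is not None and not (
            self.first_year < self.regime_year <= last
        ):
            raise ConfigurationError(
                f"regime_year {self.regime_year} outside simulated span "
                f"({self.first_year}-{last})"
            )


class SimulatedStock(NamedTuple):
    series: CPUESeries
    biomass: np.ndarray
    truth: dict


def _harvest_fractions(config: SPMSimConfig) -> np.ndarray:
    """Per-year harvest rate (fraction of current biomass caught)."""
    n, r = config.n_years, config.r_true
    if config.harvest_pattern == "constant_fraction":
        return np.full(n, r / 2.0)
    if config.harvest_pattern == "one_way":
        return np.linspace(0.02, 0.8 * r, n)
    # up_down: build-up to a peak at 60% of the series, then decline
    peak = max(int(0.6 * n), 1)
    up = np.linspace(0.02, 0.8 * r, peak)
    down = np.linspace(0.8 * r, 0.3 * r, n - peak)
    return np.concatenate([up, down])


def simulate_spm_series(config: SPMSimConfig) -> SimulatedStock:
    """Forward-simulate biomass, catch and noisy CPUE for one stock.

    Biomass follows the Schaefer update under the configured harvest;
    CPUE_t = q(t) B_t exp(eps_t) with eps_t ~ Normal(0, sigma_obs^2) and
    q switching at the regime year. Configurations whose harvest drives
    biomass below 1e-3 K are rejected with an error naming the year
    (rather than silently truncated), keeping simulated data inside the
    fitted model's support.
    """
    rng = np.random.default_rng([config.seed, 201])
    n = config.n_years
    years = np.arange(config.first_year, config.first_year + n)
    r, K = config.r_true, config.K_true

    if config.catch_series is not None:
        catch = np.asarray(config.catch_series, dtype=float)
        if len(catch) != n:
            raise ConfigurationError("catch_series length must equal n_years")
        fractions = None
    else:
        fractions = _harvest_fractions(config)
        catch = np.empty(n)

    B = np.empty(n)
    B[0] = config.initial_depletion * K
    for t in range(n):
        if fractions is not None:
            catch[t] = fractions[t] * B[t]
        if t < n - 1:
            nxt = B[t] + r * B[t] * (1.0 - B[t] / K) - catch[t]
            if config.process_error_sd > 0:
                nxt *= rng.lognormal(
                    -config.process_error_sd**2 / 2, config.process_error_sd
                )
            if nxt < 1e-3 * K:
                raise SimulationError(
                    f"harvest drives biomass below 1e-3*K in year {years[t + 1]}"
                )
            B[t + 1] = nxt

    if config.regime_year is None:
        q = np.full(n, config.q_pre)
    else:
        q = np.where(years < config.regime_year, config.q_pre, config.q_post)
    if config.efficiency_trend_pct:
        q = q * (1.0 + config.efficiency_trend_pct / 100.0) ** (years - years[0])

    cpue = q * B
    if config.sigma_obs > 0:
        cpue = cpue * np.exp(config.sigma_obs * rng.standard_normal(n))

    series = CPUESeries(
        stock_id=config.stock_id,
        years=years,
        catch=catch,
        cpue=cpue,
        regime_year=config.regime_year,
    )
    truth = {
        "r": r,
        "K": K,
        "q_pre": config.q_pre,
        "q_post": config.q_post,
        "sigma_obs": config.sigma_obs,
        "msy": r * K / 4.0,
        "final_depletion": float(B[-1] / K),
    }
    return SimulatedStock(series=series, biomass=B, truth=truth)
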