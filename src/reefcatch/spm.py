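"""Bayesian Schaefer surplus-production model on catch + CPUE series.

Biomass follows the discrete logistic (Schaefer) recursion

    B_1 = psi * K,    B_{t+1} = B_t + r B_t (1 - B_t / K) - C_t,

with catch C_t in tonnes and a floor at 1e-6 K (a floor hit flags an
implausible parameter/catch combination and zeroes the likelihood). The
observation model is lognormal CPUE around the biomass index,

    cpue_t ~ Lognormal(log(q(t) B_t), sigma_obs^2),

with catchability q(t) switching from q_pre to q_post at a configured
regime year (here, the 2004 rezoning/line-fishery restructure), and an
optional multiplicative fishing-efficiency trend of e%/yr applied to
both regimes. The management reference point is MSY = rK/4, the yield at
B = K/2.

Posterior sampling uses adaptive random-walk Metropolis on
log-transformed parameters (4 chains); fits failing the convergence gate
(split R-hat < 1.05, total bulk ESS >= 400) raise with diagnostics
attached. MSY and final-year depletion B_T/K are derived per draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._mcmc import adaptive_metropolis, diagnostics
from .errors import ConvergenceError, DataError, DomainError

__all__ = [
    "CPUESeries",
    "SPMParameters",
    "SPMPriors",
    "MCMCConfig",
    "SPMPosterior",
    "project_biomass",
    "expected_cpue",
    "log_likelihood",
    "fit_spm",
    "depletion_summary",
    "fit_r_squared",
]

BIOMASS_FLOOR_FRAC = 1e-6


@dataclass
class CPUESeries:
    """Annual catch and standardised CPUE for one stock.

    Years must be consecutive; catch must be complete, CPUE may contain
    NaN gaps (skipped in the likelihood). ``regime_year`` marks the first
    year governed by the post-change catchability (None = single q).
    """

    stock_id: str
    years: np.ndarray
    catch: np.ndarray
    cpue: np.ndarray
    regime_year: int | None = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.catch = np.asarray(self.catch, dtype=float)
        self.cpue = np.asarray(self.cpue, dtype=float)
        n = len(self.years)
        if not (len(self.catch) == len(self.cpue) == n):
            raise DomainError("years, catch and cpue must have equal length")
        if n >= 2 and not np.all(np.diff(self.years) == 1):
            raise DomainError("years must be consecutive calendar years")
        if np.any(~np.isfinite(self.catch)) or np.any(self.catch < 0):
            raise DomainError("catch must be complete and non-negative")
        observed = ~np.isnan(self.cpue)
        if np.any(self.cpue[observed] <= 0):
            raise DomainError("observed CPUE values must be positive")

    @property
    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.cpue)))


@dataclass(frozen=True)
class SPMParameters:
    """Schaefer model parameters for one stock."""

    r: float          # intrinsic growth rate, 1/yr
    K: float          # carrying capacity, tonnes
    q_pre: float      # catchability before the regime year, index/tonne
    q_post: float     # catchability from the regime year on
    sigma_obs: float  # lognormal observation sd on CPUE
    psi: float = 1.0  # initial depletion B_1/K

    def __post_init__(self):
        for name in ("r", "K", "q_pre", "q_post", "psi"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.sigma_obs < 0:
            raise DomainError("sigma_obs must be non-negative")
        if self.psi > 1:
            raise DomainError("initial depletion psi cannot exceed 1")

    @property
    def msy(self) -> float:
        return self.r * self.K / 4.0


@dataclass
class SPMPriors:
    """Weakly informative priors on the Schaefer parameters.

    r is lognormal around 0.3/yr (moderate productivity for reef
    meso-predators); K is lognormal around 5x the maximum observed catch
    (set at fit time when ``K_mu`` is None); catchabilities carry
    improper uniform priors on the log scale; sigma_obs is half-normal;
    initial depletion is uniform on [psi_low, psi_high].
    """

    r_mu: float = float(np.log(0.3))
    r_sd: float = 0.5
    K_mu: float | None = None
    K_sd: float = 1.0
    sigma_scale: float = 0.3
    psi_low: float = 0.2
    psi_high: float = 1.0


@dataclass
class MCMCConfig:
    chains: int = 4
    warmup: int = 2000
    draws: int = 4000
    target_accept: float = 0.3
    rhat_max: float = 1.05
    ess_min: float = 400.0
    max_doublings: int = 2
    seed: int = 0


@dataclass
class SPMPosterior:
    """Joint posterior draws with per-draw derived quantities.

    ``draws`` holds columns r, K, q_pre, q_post, sigma_obs, psi plus the
    derived msy (= r K / 4) and depletion (= B_T / K), all recomputable
    from the raw parameter draws. Diagnostics carry split R-hat, bulk
    ESS and per-chain acceptance rates.
    """

    stock_id: str
    draws: pd.DataFrame
    diagnostics: dict
    series: CPUESeries
    efficiency_trend_pct: float = 0.0
    n_chains: int = 4

    def median_params(self) -> SPMParameters:
        m = self.draws.median()
        return SPMParameters(
            r=m["r"], K=m["K"], q_pre=m["q_pre"], q_post=m["q_post"],
            sigma_obs=m["sigma_obs"], psi=m["psi"],
        )


def project_biomass(
    params: SPMParameters, catch: np.ndarray, n_years: int
) -> tuple[np.ndarray, bool]:
    """Deterministic Schaefer biomass trajectory under an observed catch.

    Returns the biomass vector of length ``n_years`` (B_1 = psi K) and a
    flag marking whether the floor at 1e-6 K was hit. ``catch`` supplies
    C_1..C_{n-1}; a catch vector of full length n is accepted, its last
    element being irrelevant to the projection.
    """
    catch = np.asarray(catch, dtype=float)
    if len(catch) < n_years - 1:
        raise DomainError(
            f"need at least {n_years - 1} catch values, got {len(catch)}"
        )
    B = np.empty(n_years)
    B[0] = params.psi * params.K
    floor = BIOMASS_FLOOR_FRAC * params.K
    floor_hit = False
    r, K = params.r, params.K
    for t in range(n_years - 1):
        b = B[t]
        # growth and catch are grouped so that exact equilibria (catch
        # equal to surplus production) leave biomass bit-identical
        nxt = b + (r * b * (1.0 - b / K) - catch[t])
        if nxt < floor:
            nxt = floor
            floor_hit = True
        B[t + 1] = nxt
    return B, floor_hit


def _q_vector(params, years, regime_year, efficiency_trend_pct):
    years = np.asarray(years)
    if regime_year is None:
        q = np.full(len(years), params.q_pre)
    else:
        q = np.where(years < regime_year, params.q_pre, params.q_post)
    if efficiency_trend_pct:
        q = q * (1.0 + efficiency_trend_pct / 100.0) ** (years - years[0])
    return q


def expected_cpue(
    params: SPMParameters,
    biomass: np.ndarray,
    years: np.ndarray,
    regime_year: int | None = None,
    efficiency_trend_pct: float = 0.0,
) -> np.ndarray:
    """Median CPUE index q(t) B_t.

    Years strictly before the regime year use q_pre; the regime year
    itself and later years use q_post. With a fishing-efficiency trend of
    e%/yr both regimes are scaled by (1+e/100)^(t - t_1).
    """
    biomass = np.asarray(biomass, dtype=float)
    if len(biomass) != len(years):
        raise DomainError("biomass and years must have equal length")
    return _q_vector(params, years, regime_year, efficiency_trend_pct) * biomass


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def log_likelihood(
    params: SPMParameters,
    series: CPUESeries,
    efficiency_trend_pct: float = 0.0,
) -> float:
    """Lognormal observation log-likelihood of a CPUE series.

    Gap years contribute nothing; a trajectory that hits the biomass
    floor is assigned -inf (outside the model's support).
    """
    n = len(series.years)
    B, floor_hit = project_biomass(params, series.catch, n)
    if floor_hit:
        return -np.inf
    mu = expected_cpue(
        params, B, series.years, series.regime_year, efficiency_trend_pct
    )
    obs = ~np.isnan(series.cpue)
    if not np.any(obs):
        return 0.0
    sigma = params.sigma_obs
    if sigma <= 0:
        exact = np.allclose(series.cpue[obs], mu[obs])
        return np.inf if exact else -np.inf
    z = (np.log(series.cpue[obs]) - np.log(mu[obs])) / sigma
    return float(
        np.sum(-0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI - np.log(series.cpue[obs]))
    )


# ---------------------------------------------------------------------------
# posterior sampling
#
# The sampler works on theta = (log r, log K, log sigma, psi). The
# catchabilities carry flat priors on the log scale and enter the
# likelihood as pure location parameters of the log-CPUE residuals, so
# they are integrated out analytically in the sampled target and drawn
# afterwards from their exact Gaussian conditionals, one per regime
# block. This removes the q-K ridge that cripples a plain random walk.


def _project_raw(r, K, psi, catch, n):
    """Schaefer projection on raw floats; returns (biomass, floor_hit)."""
    B = np.empty(n)
    B[0] = psi * K
    floor = BIOMASS_FLOOR_FRAC * K
    hit = False
    for t in range(n - 1):
        b = B[t]
        # growth and catch are grouped so that exact equilibria (catch
        # equal to surplus production) leave biomass bit-identical
        nxt = b + (r * b * (1.0 - b / K) - catch[t])
        if nxt < floor:
            nxt = floor
            hit = True
        B[t + 1] = nxt
    return B, hit


def _log_prior_theta(theta, priors):
    logr, logK, logsig, psi = theta
    if not priors.psi_low <= psi <= priors.psi_high:
        return -np.inf
    lp = -0.5 * ((logr - priors.r_mu) / priors.r_sd) ** 2
    lp += -0.5 * ((logK - priors.K_mu) / priors.K_sd) ** 2
    sigma = np.exp(logsig)
    # half-normal on sigma plus the log-transform Jacobian
    lp += -0.5 * (sigma / priors.sigma_scale) ** 2 + logsig
    # psi uniform on its bounds; flat log-q priors contribute nothing
    return lp


def fit_spm(
    series: CPUESeries,
    priors: SPMPriors | None = None,
    mcmc: MCMCConfig | None = None,
    efficiency_trend_pct: float = 0.0,
) -> SPMPosterior:
    """Sample the joint posterior of the Schaefer parameters by MCMC.

    Runs ``mcmc.chains`` adaptive random-walk Metropolis chains on
    (log r, log K, log sigma, psi), with the catchability (or the pre-
    and post-regime catchabilities) integrated out of the target under
    their flat log-scale priors and re-sampled from their Gaussian
    conditionals per retained draw. If the convergence gate fails,
    warmup and draws are doubled (up to ``max_doublings`` times) before
    a ConvergenceError is raised with the offending diagnostics.

    Raises
    ------
    DataError
        If no CPUE observation is present, or a catchability regime has
        no observed year at all.
    ConvergenceError
        If R-hat/ESS gates fail at the largest configured run length.
    """
    priors = priors or SPMPriors()
    mcmc = mcmc or MCMCConfig()
    if series.n_observed == 0:
        raise DataError(f"{series.stock_id}: CPUE series has no observations")
    if series.n_observed < 10:
        warnings.warn(
            f"{series.stock_id}: only {series.n_observed} observed CPUE years; "
            "parameters will be weakly identified",
            stacklevel=2,
        )
    if priors.K_mu is None:
        priors = replace(priors, K_mu=float(np.log(5.0 * np.max(series.catch))))

    has_regime = series.regime_year is not None
    obs = ~np.isnan(series.cpue)
    if has_regime:
        blocks = [obs & (series.years < series.regime_year),
                  obs & (series.years >= series.regime_year)]
    else:
        blocks = [obs]
    n_blocks = [int(m.sum()) for m in blocks]
    if any(nb == 0 for nb in n_blocks):
        raise DataError(
            f"{series.stock_id}: each catchability regime needs at least one "
            "observed CPUE year"
        )

    n = len(series.years)
    trend_log = (series.years - series.years[0]) * np.log1p(
        efficiency_trend_pct / 100.0
    )
    logc = np.where(obs, np.log(np.where(obs, series.cpue, 1.0)), 0.0)
    # detrended log CPUE: model is logc_adj = log q_j + log B_t + noise
    logc_adj = logc - trend_log
    const = -float(np.sum(logc[obs]))  # lognormal Jacobian
    catch = series.catch
    names = ["log_r", "log_K", "log_sigma", "psi"]
    d = 4

    def log_post(theta):
        lp = _log_prior_theta(theta, priors)
        if not np.isfinite(lp):
            return -np.inf
        r, K = np.exp(theta[0]), np.exp(theta[1])
        sigma = np.exp(theta[2])
        B, hit = _project_raw(r, K, theta[3], catch, n)
        if hit:
            return -np.inf
        resid = logc_adj - np.log(B)
        ll = const
        for mask, nb in zip(blocks, n_blocks):
            rb = resid[mask]
            S = float(np.sum((rb - rb.mean()) ** 2))
            ll += (
                -(nb - 1) * (theta[2] + _LOG_SQRT_2PI)
                - 0.5 * np.log(nb)
                - S / (2.0 * sigma * sigma)
            )
        return ll + lp

    # data-driven chain centre; K is walked upward until the catch
    # history is supportable (no biomass-floor hit)
    x_center = np.array([priors.r_mu, priors.K_mu, np.log(0.1), 0.8])
    for k_offset in np.arange(0.0, 3.1, 0.25):
        x_center[1] = priors.K_mu + k_offset
        if np.isfinite(log_post(x_center)):
            break

    # cheap posterior-mode search so every chain starts near the ridge
    from scipy.optimize import minimize

    opt = minimize(
        lambda th: -log_post(th), x_center, method="Nelder-Mead",
        options={"maxfev": 2000, "xatol": 1e-4, "fatol": 1e-4},
    )
    if np.isfinite(opt.fun):
        x_center = opt.x

    rng = np.random.default_rng(mcmc.seed)
    warmup, draws = mcmc.warmup, mcmc.draws
    diag = {}
    for attempt in range(mcmc.max_doublings + 1):
        chains = np.empty((mcmc.chains, draws, d))
        accept = []
        for c in range(mcmc.chains):
            for _ in range(200):
                x0 = x_center + np.array([0.2, 0.2, 0.2, 0.05]) * \
                    rng.standard_normal(d)
                if np.isfinite(log_post(x0)):
                    break
            else:
                raise ConvergenceError(
                    f"{series.stock_id}: no finite starting point found"
                )
            ch, acc = adaptive_metropolis(
                log_post, x0, warmup, draws, rng, mcmc.target_accept
            )
            chains[c] = ch
            accept.append(acc)
        diag = diagnostics(chains, names)
        diag["acceptance"] = accept
        max_rhat = max(diag["rhat"].values())
        min_ess = min(diag["ess"].values())
        if max_rhat < mcmc.rhat_max and min_ess >= mcmc.ess_min:
            break
        warmup, draws = warmup * 2, draws * 2
    else:
        raise ConvergenceError(
            f"{series.stock_id}: R-hat {max_rhat:.3f} / ESS {min_ess:.0f} "
            f"failed the gate after {mcmc.max_doublings} doublings",
            diagnostics=diag,
        )

    flat = chains.reshape(-1, d)
    r_d = np.exp(flat[:, 0])
    K_d = np.exp(flat[:, 1])
    sig_d = np.exp(flat[:, 2])
    psi_d = flat[:, 3]

    # biomass trajectories for all retained draws (vectorised over draws)
    Bmat = np.empty((len(flat), n))
    Bmat[:, 0] = psi_d * K_d
    floor = BIOMASS_FLOOR_FRAC * K_d
    for t in range(n - 1):
        b = Bmat[:, t]
        Bmat[:, t + 1] = np.maximum(b + (r_d * b * (1.0 - b / K_d) - catch[t]), floor)

    # conditional Gaussian draw of each regime's log catchability
    logq_blocks = []
    for mask, nb in zip(blocks, n_blocks):
        resid = logc_adj[None, mask] - np.log(Bmat[:, mask])
        m = resid.mean(axis=1)
        logq_blocks.append(m + sig_d / np.sqrt(nb) * rng.standard_normal(len(flat)))
    q_pre_d = np.exp(logq_blocks[0])
    q_post_d = np.exp(logq_blocks[1]) if has_regime else q_pre_d

    params_df = pd.DataFrame(
        {
            "r": r_d,
            "K": K_d,
            "q_pre": q_pre_d,
            "q_post": q_post_d,
            "sigma_obs": sig_d,
            "psi": psi_d,
        }
    )
    params_df["msy"] = params_df["r"] * params_df["K"] / 4.0
    params_df["depletion"] = Bmat[:, -1] / K_d
    params_df.insert(0, "draw", np.tile(np.arange(draws), mcmc.chains))
    params_df.insert(0, "chain", np.repeat(np.arange(mcmc.chains), draws))

    return SPMPosterior(
        stock_id=series.stock_id,
        draws=params_df,
        diagnostics=diag,
        series=series,
        efficiency_trend_pct=efficiency_trend_pct,
        n_chains=mcmc.chains,
    )


def _final_depletion(params_df: pd.DataFrame, series: CPUESeries) -> np.ndarray:
    """Vectorised B_T/K over all posterior draws."""
    r = params_df["r"].to_numpy()
    K = params_df["K"].to_numpy()
    B = params_df["psi"].to_numpy() * K
    floor = BIOMASS_FLOOR_FRAC * K
    for t in range(len(series.years) - 1):
        B = B + r * B * (1.0 - B / K) - series.catch[t]
        B = np.maximum(B, floor)
    return B / K


def depletion_summary(posterior: SPMPosterior) -> tuple[float, float, float]:
    """(2.5%, median, 97.5%) of final-year depletion B_T/K, in percent."""
    dep = posterior.draws["depletion"].to_numpy() * 100.0
    lo, med, hi = np.percentile(dep, [2.5, 50.0, 97.5])
    return float(lo), float(med), float(hi)


def fit_r_squared(posterior: SPMPosterior, series: CPUESeries | None = None) -> float:
    """Squared correlation of observed vs predicted log CPUE.

    Prediction uses the posterior-median parameter vector. Requires at
    least three observed years.
    """
    series = series or posterior.series
    obs = ~np.isnan(series.cpue)
    if int(obs.sum()) < 3:
        raise DataError("R^2 undefined with fewer than 3 observed CPUE years")
    params = posterior.median_params()
    B, _ = project_biomass(params, series.catch, len(series.years))
    pred = expected_cpue(
        params, B, series.years, series.regime_year, posterior.efficiency_trend_pct
    )
    x = np.log(series.cpue[obs])
    y = np.log(pred[obs])
    if np.std(y) == 0 or np.std(x) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)
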