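"""Bayesian regression of category catch share on percent reef area.

Each dependence category is fitted separately: the percent of a region's
catch falling in that category (y, 0-100) is regressed on the region's
percent coral-reef area (x, 0-100) under a Gaussian likelihood,

    y_i ~ Normal(alpha + beta x_i, sigma^2),

with broad default priors: an (effectively) improper flat prior on the
intercept, Normal(0, 1000) on the slope, and a log-gamma prior on the
precision tau = 1/sigma^2 (i.e. tau ~ Gamma(shape, rate), defaults
shape 1, rate 5e-5). Sampling is Metropolis-within-Gibbs: tau by its
conjugate gamma draw, alpha and beta by adaptive scalar random walks;
4 chains gated on split R-hat < 1.05.

The headline summary is the posterior median slope together with the
posterior probability that the slope is positive (or negative) — the
form in which a weak habitat-area effect on catch composition is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mcmc import ScalarRWStep, diagnostics
from .errors import ConvergenceError, DomainError
from .habitat import DependenceCategory

__all__ = [
    "RegressionData",
    "RegressionPriors",
    "RegressionMCMC",
    "RegressionPosterior",
    "fit_linear_model",
    "probability_of_sign",
]


@dataclass
class RegressionData:
    """Percent reef area (x) vs percent catch in one category (y)."""

    x: np.ndarray
    y: np.ndarray
    category: DependenceCategory | int = DependenceCategory.NOT_ASSOCIATED

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise DomainError("x and y must have equal length")
        if len(self.x) < 3:
            raise DomainError("need at least 3 regions to fit a slope")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise DomainError("x and y must be finite")


@dataclass
class RegressionPriors:
    """Broad default priors; the intercept's flat prior is approximated
    by Normal(0, 1e8) for sampler stability."""

    intercept_var: float = 1e8
    slope_var: float = 1000.0
    precision_shape: float = 1.0
    precision_rate: float = 5e-5


@dataclass
class RegressionMCMC:
    chains: int = 4
    warmup: int = 1500
    draws: int = 2000
    rhat_max: float = 1.05
    max_doublings: int = 2
    seed: int = 0


@dataclass
class RegressionPosterior:
    """Draws of (alpha, beta, sigma) with slope summaries."""

    draws: pd.DataFrame
    diagnostics: dict
    category: DependenceCategory | int

    @property
    def beta(self) -> np.ndarray:
        return self.draws["beta"].to_numpy()

    @property
    def median_slope(self) -> float:
        return float(np.median(self.beta))

    @property
    def p_positive(self) -> float:
        return probability_of_sign(self.beta, "positive")

    @property
    def p_negative(self) -> float:
        return probability_of_sign(self.beta, "negative")

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.beta, [2.5, 97.5])
        return float(lo), float(hi)


def probability_of_sign(beta_draws: np.ndarray, direction: str) -> float:
    """Fraction of slope draws strictly on the requested side of zero."""
    beta_draws = np.asarray(beta_draws, dtype=float)
    if beta_draws.size == 0:
        raise DomainError("need at least one draw")
    if direction == "positive":
        return float(np.mean(beta_draws > 0))
    if direction == "negative":
        return float(np.mean(beta_draws < 0))
    raise DomainError("direction must be 'positive' or 'negative'")


def fit_linear_model(
    data: RegressionData,
    priors: RegressionPriors | None = None,
    mcmc: RegressionMCMC | None = None,
) -> RegressionPosterior:
    """Sample the posterior of (alpha, beta, tau) for one category.

    Raises
    ------
    DomainError
        If x is constant (slope unidentifiable).
    ConvergenceError
        If R-hat stays above the gate at the longest configured run.
    """
    priors = priors or RegressionPriors()
    mcmc = mcmc or RegressionMCMC()
    x, y = data.x, data.y
    if np.ptp(x) == 0:
        raise DomainError("x is constant: slope is not identifiable")
    n = len(x)
    rng = np.random.default_rng(mcmc.seed)

    # OLS-ish anchor for chain initialisation
    beta_hat = float(np.cov(x, y, bias=True)[0, 1] / np.var(x))
    alpha_hat = float(np.mean(y) - beta_hat * np.mean(x))
    resid_sd = max(float(np.std(y - alpha_hat - beta_hat * x)), 1e-6)

    warmup, draws = mcmc.warmup, mcmc.draws
    diag = {}
    names = ["alpha", "beta", "sigma"]
    for attempt in range(mcmc.max_doublings + 1):
        chains = np.empty((mcmc.chains, draws, 3))
        for c in range(mcmc.chains):
            alpha = alpha_hat + resid_sd * rng.standard_normal()
            beta = beta_hat + resid_sd / max(np.std(x), 1e-6) * rng.standard_normal()
            tau = 1.0 / resid_sd**2
            step_a = ScalarRWStep(scale=resid_sd / np.sqrt(n) + 1e-3)
            step_b = ScalarRWStep(scale=resid_sd / (np.std(x) * np.sqrt(n)) + 1e-3)
            for i in range(warmup + draws):
                adapt = i < warmup
                sse = float(np.sum((y - alpha - beta * x) ** 2))
                tau = rng.gamma(
                    priors.precision_shape + n / 2.0,
                    1.0 / (priors.precision_rate + sse / 2.0),
                )

                def cond_alpha(a, beta=beta, tau=tau):
                    res = y - a - beta * x
                    return -0.5 * tau * res @ res - a * a / (2 * priors.intercept_var)

                alpha = step_a.update(alpha, cond_alpha, rng, adapt)

                def cond_beta(b, alpha=alpha, tau=tau):
                    res = y - alpha - b * x
                    return -0.5 * tau * res @ res - b * b / (2 * priors.slope_var)

                beta = step_b.update(beta, cond_beta, rng, adapt)
                if i >= warmup:
                    chains[c, i - warmup] = (alpha, beta, 1.0 / np.sqrt(tau))
        diag = diagnostics(chains, names)
        max_rhat = max(diag["rhat"].values())
        if max_rhat < mcmc.rhat_max:
            break
        warmup, draws = warmup * 2, draws * 2
    else:
        raise ConvergenceError(
            f"regression R-hat {max_rhat:.3f} failed the gate", diagnostics=diag
        )

    flat = chains.reshape(-1, 3)
    df = pd.DataFrame(flat, columns=names)
    df.insert(0, "draw", np.tile(np.arange(draws), mcmc.chains))
    df.insert(0, "chain", np.repeat(np.arange(mcmc.chains), draws))
    return RegressionPosterior(draws=df, diagnostics=diag, category=data.category)
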