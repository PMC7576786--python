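"""Random-walk MCMC building blocks shared by the model-fitting modules.

Samplers are deliberately simple and transparent: adaptive random-walk
Metropolis with a Haario-style empirical proposal covariance for the
surplus-production model, and scalar adaptive random-walk steps for the
Metropolis-within-Gibbs regression. Convergence is judged with
rank-normalised split R-hat and effective sample size from arviz.
"""

from __future__ import annotations

import warnings

import arviz as az
import numpy as np

__all__ = ["adaptive_metropolis", "diagnostics", "ScalarRWStep"]


def adaptive_metropolis(
    log_post,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.3,
):
    """One chain of adaptive random-walk Metropolis.

    During warmup the proposal is N(0, s^2 (Sigma_hat + eps I)) where
    Sigma_hat is the running empirical covariance of the chain and the
    global scale s is tuned by stochastic approximation toward
    ``target_accept``; adaptation freezes at the end of warmup. Returns
    (draws, acceptance_rate) with draws of shape (n_draws, d).
    """
    d = len(x0)
    x = np.asarray(x0, dtype=float).copy()
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log posterior")

    log_scale = np.log(2.38 / np.sqrt(d))
    chol = np.eye(d) * 0.1
    warm = np.empty((n_warmup, d))
    draws = np.empty((n_draws, d))
    n_accept = 0
    since_refresh = 0
    for i in range(n_warmup + n_draws):
        prop = x + np.exp(log_scale) * (chol @ rng.standard_normal(d))
        lp_prop = log_post(prop)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            x, lp = prop, lp_prop
        if i < n_warmup:
            warm[i] = x
            since_refresh += 1
            log_scale += (float(accept) - target_accept) / max(since_refresh, 10) ** 0.6
            # re-estimate the proposal shape from the recent half of the
            # warmup history; discarding the early transient makes the
            # estimate robust to a poor starting point
            if i + 1 >= 200 and (i + 1) % 200 == 0:
                cov = np.cov(warm[(i + 1) // 2 : i + 1].T)
                cov = np.atleast_2d(cov) + 1e-10 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(cov)
                    since_refresh = 1
                except np.linalg.LinAlgError:
                    pass
        else:
            draws[i - n_warmup] = x
            n_accept += int(accept)
    return draws, n_accept / n_draws


def diagnostics(chains: np.ndarray, names: list[str]) -> dict:
    """Split R-hat and bulk ESS per parameter.

    ``chains`` has shape (n_chains, n_draws, d).
    """
    data = {name: chains[:, :, j] for j, name in enumerate(names)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=data)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    return {
        "rhat": {name: float(rhat[name].values) for name in names},
        "ess": {name: float(ess[name].values) for name in names},
    }


class ScalarRWStep:
    """Adaptive scalar random-walk Metropolis step for one parameter.

    Tunes its proposal sd toward the 1-D optimal acceptance rate (~0.44)
    during warmup, then freezes.
    """

    def __init__(self, scale: float = 1.0, target_accept: float = 0.44):
        self.log_scale = np.log(scale)
        self.target = target_accept
        self._k = 0

    def update(
        self, x: float, log_cond, rng: np.random.Generator, adapt: bool
    ) -> float:
        prop = x + np.exp(self.log_scale) * rng.standard_normal()
        accept = np.log(rng.random()) < log_cond(prop) - log_cond(x)
        if adapt:
            self._k += 1
            self.log_scale += (float(accept) - self.target) / max(self._k, 10) ** 0.6
        return prop if accept else x
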