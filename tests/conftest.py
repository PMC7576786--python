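import numpy as np
import pytest

import reefcatch as rc


@pytest.fixture(scope="session")
def recovered_stock():
    """A 40-year simulated stock and its fitted posterior, shared across
    tests that only need *a* converged fit."""
    sim = rc.simulate_spm_series(rc.SPMSimConfig(seed=1))
    posterior = rc.fit_spm(sim.series, mcmc=rc.MCMCConfig(seed=1))
    return sim, posterior


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
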