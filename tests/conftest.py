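import numpy as np
import pytest

import chm


@pytest.fixture(scope="session")
def theta_default():
    return chm.default_theta()


@pytest.fixture(scope="session")
def noisefree_pair(theta_default):
    """One LD+SD pair with zero noise and zero batch dispersion."""
    theta = chm.default_theta(sigma_c=1e-6, sigma_s=1e-6)
    series = chm.generate_wildtype(
        theta, chm.StudyDesign(n_batches=1, batch_dispersion=0.0, seed=0))
    return chm.pair_series(series)[0]


@pytest.fixture(scope="session")
def noisy_pair(theta_default):
    series = chm.generate_wildtype(
        theta_default,
        chm.StudyDesign(n_batches=1, batch_dispersion=0.0, seed=7))
    return chm.pair_series(series)[0]


@pytest.fixture(scope="session")
def fast_config():
    """Reduced sampler settings for unit tests."""
    return chm.SamplerConfig(chains=4, warmup=300, samples=300,
                             walkers_per_chain=6, seed=11,
                             store_pointwise=False)


def random_homeostatic_params(rng):
    """A random valid parameter set on the homeostatic orbit
    (tau_L = external photoperiod >= 1 - gamma)."""
    gamma = rng.uniform(0.3, 0.9)
    # tau = P must be >= 1 - gamma for a positive light-phase rate, and the
    # grid must divide both phases: draw P in whole hours
    p_hours = rng.integers(max(4, int(np.ceil((1 - gamma) * 24)) + 1), 21)
    P = p_hours / 24.0
    core = chm.CoreParams(a=rng.uniform(1.0, 10.0), gamma=gamma,
                          beta_p=rng.uniform(0.3, 3.0))
    cond = chm.ConditionParams(H=rng.uniform(0.5, 8.0), tau_L=P,
                               photoperiod_ext=P,
                               condition_label="LD")
    return core, cond
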