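import numpy as np
import pytest
from hypothesis import settings

import spectralcmc as s
from spectralcmc import cmc, vl

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return cmc.default_grid()


@pytest.fixture(scope="session")
def base_params():
    return cmc.CMCParameters()


@pytest.fixture(scope="session")
def base_obs():
    return cmc.ObservationParameters()


@pytest.fixture(scope="session")
def base_psd(base_params, base_obs, grid):
    return cmc.predict_psd(base_params, base_obs, grid)


def stable_draws(n, seed, scale=1.0):
    """Random neuronal/observation parameter draws with stable Jacobians."""
    rng = np.random.default_rng(seed)
    base = cmc.pack_parameters(cmc.CMCParameters(), cmc.ObservationParameters())
    sd = np.sqrt(np.diag(vl.default_prior().covariance)) * scale
    draws = []
    while len(draws) < n:
        vec = base + rng.normal(0.0, sd)
        params, obs = cmc.unpack_parameters(vec)
        if np.linalg.eigvals(cmc.linearize(params)).real.max() < 0:
            draws.append((params, obs))
    return draws


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort for integration tests."""
    return s.generate_cohort(
        s.CohortConfig(n_regions=10, channels_per_region=2), seed=5)


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohort):
    return [vl.fit_channel(psd) for psd in small_cohort.spectra]
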