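import numpy as np
import pytest

import ramandx as r


@pytest.fixture(scope="session")
def axis():
    return r.make_axis(400.0, 1800.0, 1.0)


@pytest.fixture(scope="session")
def noiseless_config():
    """Default study conditions with noise switched off and a small cohort."""
    return r.default_config(noise_sd=0.0, n_per_class=3)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return r.simulate_cohort(noiseless_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_spectrum(axis, rng, scale=50.0):
    """Non-negative random spectrum used by baseline/normalization tests."""
    y = rng.gamma(2.0, scale, size=len(axis))
    return r.RamanSpectrum(axis, y)
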