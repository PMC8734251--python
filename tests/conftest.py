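import numpy as np
import pytest

from agsevnet import PhantomConfig, generate_case


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom_config():
    """Deterministic 24^3 phantom used across unit tests."""
    return PhantomConfig(
        volume_shape=(24, 24, 24),
        region_radii=(7.0, 4.0, 2.0),
        center_jitter=1.0,
        noise_sd=5.0,
        seed=11,
        n_cases=3,
    )


@pytest.fixture(scope="session")
def small_phantom_case(small_phantom_config):
    return generate_case(small_phantom_config, 0)
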