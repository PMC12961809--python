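import numpy as np
import pytest

from posam_ultra import NetworkConfig, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom64():
    """One deterministic 64x64 phantom with a single 5% tumor."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_cfg():
    return NetworkConfig(base_filters=8, n_stages=3, cbam_reduction=4,
                         dropout=0.0, seed=0)
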