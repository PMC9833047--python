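import numpy as np
import pytest
from hypothesis import settings

from infomaxstdp.network import NetworkConfig

# property tests must behave identically on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from infomaxstdp.params import PlasticityParams
from infomaxstdp.single_neuron import FeedforwardConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ff_config():
    return FeedforwardConfig()


@pytest.fixture(scope="session")
def plasticity():
    return PlasticityParams()


@pytest.fixture(scope="session")
def net_config():
    return NetworkConfig()


@pytest.fixture(scope="session")
def small_net_config():
    """A structurally identical but tiny network for fast structural tests."""
    return NetworkConfig(n_E=80, n_I=20)
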