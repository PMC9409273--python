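import numpy as np
import pytest

from vesicalc import channel_model as cm
from vesicalc import secretion_sim as sim


@pytest.fixture(scope="session")
def params() -> cm.ChannelParams:
    return cm.ChannelParams()


@pytest.fixture(scope="session")
def graph(params) -> cm.RateGraph:
    return cm.build_rate_graph(params)


@pytest.fixture(scope="session")
def cone() -> sim.ConeDomain:
    """Default cone (1 µm base, 5 µm height, 70 nm grid), built once."""
    return sim.discretize_cone()


@pytest.fixture(scope="session")
def small_cone() -> sim.ConeDomain:
    return sim.discretize_cone(base_radius=0.5, height=1.0, dx=0.07)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
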