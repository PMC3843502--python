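import numpy as np
import pytest

from toewalk import build_model
from toewalk.control import GainConfig, StepTarget
from toewalk.hybrid_sim import SimConfig


@pytest.fixture(scope="session")
def model():
    return build_model()


@pytest.fixture(scope="session")
def gains():
    return GainConfig.from_omega()


@pytest.fixture(scope="session")
def target():
    return StepTarget()


@pytest.fixture(scope="session")
def simcfg():
    return SimConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
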