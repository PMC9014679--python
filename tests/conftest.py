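import numpy as np
import pytest

from cmrkit import KineticParams, StudyConfig
from cmrkit.synth import make_phantom


@pytest.fixture
def config():
    return StudyConfig()

@pytest.fixture
def params():
    return KineticParams()


@pytest.fixture(scope="session")
def phantom():
    return make_phantom()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
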