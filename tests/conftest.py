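import numpy as np
import pytest

from nfbloop.fixtures import make_latency_fixture, make_outcome_fixture
from nfbloop.paradigm import SessionConfig


@pytest.fixture(scope="session")
def default_config():
    return SessionConfig(rng_seed=7)


@pytest.fixture(scope="session")
def outcome_fixture():
    return make_outcome_fixture()


@pytest.fixture(scope="session")
def latency_fixture():
    return make_latency_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
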