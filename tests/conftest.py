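import numpy as np
import pytest

from rh2evol import build_rate_matrix, fixture_fig1, fixture_table1, get_model


@pytest.fixture(scope="session")
def jtt():
    return build_rate_matrix(get_model("JTT"))


@pytest.fixture(scope="session")
def wag():
    return build_rate_matrix(get_model("WAG"))


@pytest.fixture(scope="session")
def fig1():
    return fixture_fig1()


@pytest.fixture(scope="session")
def table1():
    return fixture_table1()


@pytest.fixture
def rng():
    return np.random.default_rng(20201)
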