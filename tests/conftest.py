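import numpy as np
import pytest
from hypothesis import settings

from canmicro import ModelParams

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return ModelParams.table1()


@pytest.fixture(scope="session")
def two_pop():
    return ModelParams.two_population()


@pytest.fixture(scope="session")
def disinhibited():
    return ModelParams.two_population_disinhibited()


@pytest.fixture(scope="session")
def default_branch(table1):
    """Default fixed-point branch, shared across tests (deterministic)."""
    from canmicro import continue_branch
    return continue_branch((-50.0, 120.0), table1)


@pytest.fixture(scope="session")
def zero_gain_params():
    return ModelParams.table1().replace(
        N_EP=0.0, N_PE=0.0, N_IP=0.0, N_PI=0.0, N_PP=0.0, N_II=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
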