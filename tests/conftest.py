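import numpy as np
import pytest

from smacsim.boundary import BoundaryCondition
from smacsim.grid import Grid
from smacsim.parameters import default_parameters, dimensionless_groups


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def groups(params):
    return dimensionless_groups(params)


@pytest.fixture(scope="session")
def periodic32():
    return Grid(32)


@pytest.fixture(scope="session")
def disk32():
    return Grid(32, "disk")


@pytest.fixture(scope="session")
def bc_open():
    return BoundaryCondition("open_pinned")


@pytest.fixture(scope="session")
def bc_closed():
    return BoundaryCondition("closed_free")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
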