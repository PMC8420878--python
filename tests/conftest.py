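import numpy as np
import pytest

from hsicurve.inversion import FitConfig, ForwardModel
from hsicurve.optics import default_tables, default_wavelength_grid


@pytest.fixture(scope="session")
def grid():
    return default_wavelength_grid()


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture(scope="session")
def fm_phantom(grid):
    return ForwardModel("phantom", grid, FitConfig(model="phantom"))


@pytest.fixture(scope="session")
def fm_skin(grid):
    return ForwardModel("skin", grid, FitConfig(model="skin"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
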