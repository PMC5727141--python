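import numpy as np
import pytest

from polarphase.models import make_model
from polarphase import reduction


@pytest.fixture(scope="session")
def gle_model():
    return make_model("gle")


@pytest.fixture(scope="session")
def ai_model():
    return make_model("activator_inhibitor")


@pytest.fixture(scope="session")
def gle_cell(gle_model):
    return reduction.reduce_cell(gle_model, n_theta=256)


@pytest.fixture(scope="session")
def ai_cell(ai_model):
    return reduction.reduce_cell(ai_model, n_theta=256)


@pytest.fixture(scope="session")
def gle_fd(gle_cell):
    return reduction.fourier_coefficients(gle_cell, K=8)


@pytest.fixture(scope="session")
def ai_fd(ai_cell):
    return reduction.fourier_coefficients(ai_cell, K=8)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170)
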