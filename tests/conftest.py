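import numpy as np
import pytest

from atpflux.calibration import REPORTED_CALIBRATION
from atpflux.mfa import build_network
from atpflux import synthetic


@pytest.fixture(scope="session")
def model():
    return build_network()


@pytest.fixture(scope="session")
def scenarios(model):
    return synthetic.gen_scenarios(model)


@pytest.fixture(scope="session")
def flux_vectors(model):
    return synthetic.gen_flux_scenarios(model)


@pytest.fixture(scope="session")
def calib():
    return REPORTED_CALIBRATION


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
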