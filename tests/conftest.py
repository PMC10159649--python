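import numpy as np
import pytest

from rinnet import GeometricCriteria, default_chemistry
from rinnet.fixtures import make_ideal_helix


@pytest.fixture(scope="session")
def criteria():
    return GeometricCriteria()


@pytest.fixture(scope="session")
def chemistry():
    return default_chemistry()


@pytest.fixture(scope="session")
def helix18():
    ensemble, truth = make_ideal_helix(18)
    return ensemble, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
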