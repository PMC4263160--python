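import numpy as np
import pytest

from tubuloid.geometry import SpheroidShape, charge_pair


@pytest.fixture(scope="session")
def shape():
    """The reference particle: short semi-axis 1, aspect ratio 2.7."""
    return SpheroidShape(R=1.0, rho=2.7)


@pytest.fixture(scope="session")
def pair(shape):
    return charge_pair(shape)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)
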