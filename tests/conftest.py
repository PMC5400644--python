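import numpy as np
import pytest

from ritdose.nuclides import load_nuclide


@pytest.fixture(scope="session")
def lu177():
    return load_nuclide("Lu-177")


@pytest.fixture(scope="session")
def y90():
    return load_nuclide("Y-90")


@pytest.fixture(scope="session")
def in111():
    return load_nuclide("In-111")


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
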