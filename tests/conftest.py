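import numpy as np
import pytest

from scabra.saponins import load_reference_library, load_reference_profiles
from scabra.windows import Disk


@pytest.fixture(scope="session")
def reference_profiles():
    return load_reference_profiles()


@pytest.fixture(scope="session")
def reference_library():
    return load_reference_library()


@pytest.fixture
def tank():
    """The standard 60 cm aquarium window, coordinates in cm."""
    return Disk((0.0, 0.0), 30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
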