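import numpy as np
import pytest

from magchip.field_energy import ExternalField, FilmResponse, FluidEnv
from magchip.geometry import TrackSpec, make_disk_pattern, make_drop_track


@pytest.fixture(scope="session")
def film():
    return FilmResponse()


@pytest.fixture(scope="session")
def fluid():
    return FluidEnv()


@pytest.fixture(scope="session")
def conical_field():
    """The bench drive: 70 Oe in-plane + 70 Oe vertical at 0.2 Hz."""
    return ExternalField(70.0, 70.0, 0.2)


@pytest.fixture(scope="session")
def inplane_field():
    return ExternalField(70.0, 0.0, 0.2)


@pytest.fixture(scope="session")
def canonical_track():
    return make_drop_track(TrackSpec(n_units=6))


@pytest.fixture(scope="session")
def single_disk():
    return make_disk_pattern(diameter=20.0, n_disks=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
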