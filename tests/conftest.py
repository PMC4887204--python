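import numpy as np
import pytest

from morphograd.correlation_models import ObservationVolume


@pytest.fixture(scope="session")
def volume() -> ObservationVolume:
    """Default confocal volume: omega0 = 0.25 um, z0 = 1.25 um."""
    return ObservationVolume(omega0=0.25, z0=1.25)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160421)
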