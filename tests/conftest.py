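import numpy as np
import pytest

from hphabitat import ParameterMap, TumourROI, generate_phantom
from hphabitat.phantom import default_phantom_spec, recovery_phantom_spec


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Canonical 3-habitat phantom with all noise switched off."""
    spec = default_phantom_spec(seed=11)
    spec.noise_sd = {k: 0.0 for k in spec.noise_sd}
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(default_phantom_spec(seed=23))


@pytest.fixture(scope="session")
def recovery_phantom_noiseless():
    return generate_phantom(recovery_phantom_spec(seed=5, noise_fraction=0.0))


@pytest.fixture
def small_roi():
    mask = np.zeros((8, 8), dtype=bool)
    mask[2:6, 2:6] = True
    return TumourROI(mask, "0", "P0")


@pytest.fixture
def uniform_maps(small_roi):
    def make(value, kind):
        return ParameterMap(np.full((8, 8), float(value)), kind)

    return make
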