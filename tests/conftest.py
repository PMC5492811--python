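import numpy as np
import pytest

from canopytrait import (
    SimulationConfig,
    Spectrum,
    ground_band_set,
    uav_band_set,
)


@pytest.fixture(scope="session")
def uav_bs():
    return uav_band_set()


@pytest.fixture(scope="session")
def ground_bs():
    return ground_band_set()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cfg():
    return SimulationConfig(seed=7)


def spectrum_at(band_set, **reflectances):
    """Spectrum with a low baseline and explicit values at named bands.

    ``spectrum_at(bs, R670=0.05, R800=0.45)`` sets the bands nearest
    670 and 800 nm and 0.05 elsewhere.
    """
    values = np.full(len(band_set), 0.05)
    for key, val in reflectances.items():
        nominal = float(key.lstrip("R"))
        pos = int(np.argmin(np.abs(band_set.centers - nominal)))
        values[pos] = val
    return Spectrum(band_set, values)


@pytest.fixture
def make_spectrum(uav_bs):
    def _make(**kw):
        return spectrum_at(uav_bs, **kw)

    return _make
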