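import numpy as np
import pytest

from lovscreen.simulate import GeneratorConfig
from lovscreen.spectra import EmissionSpectrum


@pytest.fixture
def config():
    return GeneratorConfig(seed=7)


@pytest.fixture
def grid():
    return np.arange(470.0, 601.0, 1.0)


@pytest.fixture
def flat_spectrum(grid):
    return EmissionSpectrum(wavelengths=grid, intensities=np.ones_like(grid))


def gaussian_spectrum(grid, peak_nm=495.0, amplitude=100.0, sigma=15.0, **meta):
    intensities = amplitude * np.exp(-((grid - peak_nm) ** 2) / (2 * sigma**2))
    return EmissionSpectrum(wavelengths=grid, intensities=intensities, **meta)
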