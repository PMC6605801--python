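import numpy as np
import pytest

from ktquant.core import CalibrationStandard, NoiseModel, PSFModel


@pytest.fixture
def calib() -> CalibrationStandard:
    return CalibrationStandard(single_gfp_amplitude=150.0, power_ratio=1.0)


@pytest.fixture
def sim_psf() -> PSFModel:
    return PSFModel(fwhm_lateral=119.0, fwhm_axial=272.0)


@pytest.fixture
def camera_noise() -> NoiseModel:
    return NoiseModel(gain=1.0, read_noise_sd=10.0)


def measure_fwhm(profile: np.ndarray, pitch: float) -> float:
    """Linear-interpolated full width at half maximum of a 1D profile."""
    m = profile.max() / 2.0
    above = profile >= m
    i0 = int(np.argmax(above))
    i1 = len(profile) - 1 - int(np.argmax(above[::-1]))
    left = i0 - 1 + (m - profile[i0 - 1]) / (profile[i0] - profile[i0 - 1])
    right = i1 + (m - profile[i1]) / (profile[i1 + 1] - profile[i1])
    return (right - left) * pitch
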