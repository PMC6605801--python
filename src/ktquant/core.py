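"""Shared domain types for kinetochore-cluster image quantification.

All physical lengths are nanometres unless a name says otherwise.  Image
volumes are stored in (z, y, x) order with y the spindle axis, so that a
"vertical" profile in an aligned image runs along the spindle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Conversion between Gaussian full width at half maximum and standard
#: deviation: FWHM = 2*sqrt(2*ln 2) * sigma.
FWHM_PER_SIGMA: float = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Default lateral pixel pitch (nm) of the quantitative-imaging camera.
#: Derived from the equivalence of a 245 nm Gaussian SD with 1.75 pixels.
DEFAULT_PITCH_XY: float = 140.0

#: Default z step (nm) of quantitative-imaging stacks.
DEFAULT_PITCH_Z: float = 300.0

#: Kinetochores per clustered spot: one microtubule per chromosome,
#: 16 chromosomes in budding yeast.
KINETOCHORES_PER_CLUSTER: int = 16


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    return sigma * FWHM_PER_SIGMA


@dataclass(frozen=True)
class PSFModel:
    """3D Gaussian approximation of the microscope focal volume.

    Parameters
    ----------
    fwhm_lateral
        Full width at half maximum (nm) in the image plane (x and y).
    fwhm_axial
        Full width at half maximum (nm) along the optical axis (z).
    """

    fwhm_lateral: float
    fwhm_axial: float

    def __post_init__(self) -> None:
        if not (self.fwhm_lateral > 0 and self.fwhm_axial > 0):
            raise ValueError("PSF FWHM values must be positive")

    @property
    def sigma_lateral(self) -> float:
        return fwhm_to_sigma(self.fwhm_lateral)

    @property
    def sigma_axial(self) -> float:
        return fwhm_to_sigma(self.fwhm_axial)


#: Focal-volume dimensions measured from SPA-SIM fiducial reconstructions
#: (lateral / axial FWHM of the mCherry channel, nm).
SIM_PSF = PSFModel(fwhm_lateral=119.0, fwhm_axial=272.0)


@dataclass
class ImageVolume:
    """A single-channel 3D intensity grid with physical voxel pitch.

    ``voxels`` is indexed (z, y, x); ``pitch_xy`` applies to both in-plane
    axes and ``pitch_z`` to the slice spacing.
    """

    voxels: np.ndarray
    pitch_xy: float = DEFAULT_PITCH_XY
    pitch_z: float = DEFAULT_PITCH_Z
    channel: str = "GFP"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        if min(self.voxels.shape) < 1:
            raise ValueError("every dimension must be >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        if not (self.pitch_xy > 0 and self.pitch_z > 0):
            raise ValueError("voxel pitches must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_to_nm(self, zyx: tuple[float, float, float]) -> tuple[float, float, float]:
        """Convert (z, y, x) voxel indices to (x, y, z) physical coordinates."""
        z, y, x = zyx
        return (x * self.pitch_xy, y * self.pitch_xy, z * self.pitch_z)

    def nm_to_voxel(self, xyz: tuple[float, float, float]) -> tuple[float, float, float]:
        """Convert (x, y, z) physical coordinates to (z, y, x) voxel indices."""
        x, y, z = xyz
        return (z / self.pitch_z, y / self.pitch_xy, x / self.pitch_xy)

    def copy(self) -> "ImageVolume":
        return ImageVolume(
            self.voxels.copy(), pitch_xy=self.pitch_xy, pitch_z=self.pitch_z, channel=self.channel
        )


@dataclass(frozen=True)
class CalibrationStandard:
    """Brightness of one GFP molecule under the imaging configuration.

    ``single_gfp_amplitude`` is the fitted Gaussian amplitude (camera
    intensity units) predicted for a single GFP from the FCS-measured
    concentration of a cytosolic-GFP strain.  ``power_ratio`` rescales
    images acquired at reduced laser power back to calibration power.
    """

    single_gfp_amplitude: float
    power_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not self.single_gfp_amplitude > 0:
            raise ValueError("single-GFP amplitude must be positive")
        if not self.power_ratio > 0:
            raise ValueError("power ratio must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson photon noise plus Gaussian read noise.

    Intensities are divided by ``gain`` (camera units per photon) before
    Poisson sampling and multiplied back; zero-mean Gaussian read noise of
    SD ``read_noise_sd`` (camera units) is then added and the result is
    clipped at zero.  ``gain = 0`` disables photon noise.
    """

    gain: float = 1.0
    read_noise_sd: float = 0.0

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noisy = np.asarray(clean, dtype=float)
        if self.gain > 0:
            noisy = rng.poisson(np.maximum(noisy, 0.0) / self.gain) * self.gain
        if self.read_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, self.read_noise_sd, size=noisy.shape)
        return np.clip(noisy, 0.0, None)


NOISELESS = NoiseModel(gain=0.0, read_noise_sd=0.0)
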