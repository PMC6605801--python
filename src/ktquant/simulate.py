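"""Synthetic fluorescence-imaging data with known ground truth.

Everything the downstream analysis consumes can be generated here:
Gaussian PSF kernels, PSF-convolved cylinder volumes emulating radially
arranged kinetochores, calibrated single-spot images for molecule
counting, two-channel particle populations for single-particle averaging,
and step-bleach FRAP time courses.  Each generator is deterministic given
its ground-truth parameters and a seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import (
    NOISELESS,
    CalibrationStandard,
    ImageVolume,
    NoiseModel,
    PSFModel,
    SIM_PSF,
    fwhm_to_sigma,
)

__all__ = [
    "CylinderSpec",
    "ClusterSpotTruth",
    "PopulationTruth",
    "SyntheticParticle",
    "FrapSeriesTruth",
    "render_psf",
    "simulate_cylinder_image",
    "simulate_cluster_spot",
    "simulate_particle_population",
    "simulate_frap_series",
]


# ---------------------------------------------------------------------------
# PSF rendering


def render_psf(
    psf: PSFModel, pitch_xy: float, pitch_z: float, truncate_sigmas: float = 4.0
) -> ImageVolume:
    """Render a normalized 3D Gaussian kernel on a voxel grid.

    The grid covers ±``truncate_sigmas`` standard deviations in every axis
    and the kernel is normalized to unit sum.  The pitch must satisfy the
    Nyquist-like condition pitch <= FWHM/2 in each axis, otherwise the
    rendered kernel would alias the requested width.
    """
    if pitch_xy > psf.fwhm_lateral / 2 or pitch_z > psf.fwhm_axial / 2:
        raise ValueError(
            f"undersampled PSF: pitch ({pitch_xy}, {pitch_z}) nm exceeds half the "
            f"FWHM ({psf.fwhm_lateral}, {psf.fwhm_axial}) nm"
        )
    sig_xy = psf.sigma_lateral
    sig_z = psf.sigma_axial
    half_xy = int(math.ceil(truncate_sigmas * sig_xy / pitch_xy))
    half_z = int(math.ceil(truncate_sigmas * sig_z / pitch_z))
    x = np.arange(-half_xy, half_xy + 1) * pitch_xy
    z = np.arange(-half_z, half_z + 1) * pitch_z
    gx = np.exp(-0.5 * (x / sig_xy) ** 2)
    gz = np.exp(-0.5 * (z / sig_z) ** 2)
    kernel = gz[:, None, None] * gx[None, :, None] * gx[None, None, :]
    kernel /= kernel.sum()
    return ImageVolume(kernel, pitch_xy=pitch_xy, pitch_z=pitch_z, channel="psf")


# ---------------------------------------------------------------------------
# Cylinder forward simulation


@dataclass(frozen=True)
class CylinderSpec:
    """Geometry of stacked kinetochore rings plus imaging parameters.

    ``n_rings`` circles of ``diameter`` lie in planes perpendicular to the
    spindle (y) axis, centres spaced ``ring_spacing`` apart along y, on an
    isotropic grid of ``grid_pitch``.  An optional extra 3D Gaussian blob
    (``fin1_blob`` = (x, y, z, amplitude, sigma) in nm) emulates a
    pole-proximal protein signal.
    """

    n_rings: int = 4
    ring_spacing: float = 75.0
    diameter: float = 250.0
    grid_pitch: float = 5.0
    psf: PSFModel = SIM_PSF
    fin1_blob: tuple[float, float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")
        if self.diameter < 0:
            raise ValueError("diameter must be >= 0")
        if not self.grid_pitch > 0:
            raise ValueError("grid_pitch must be positive")


def _deposit_ring(
    volume: np.ndarray,
    center_zyx_px: tuple[float, float, float],
    radius_px: float,
    weight: float = 1.0,
    n_samples: int = 4096,
) -> None:
    """Deposit a circle in the x–z plane with trilinear weighting.

    Sub-voxel deposition keeps the rendered ring a smooth function of its
    radius, which the diameter search relies on.
    """
    cz, cy, cx = center_zyx_px
    theta = (np.arange(n_samples) + 0.5) * (2.0 * np.pi / n_samples)
    xs = cx + radius_px * np.cos(theta)
    zs = cz + radius_px * np.sin(theta)
    ys = np.full(n_samples, cy)
    w = np.full(n_samples, weight / n_samples)
    _deposit_trilinear(volume, zs, ys, xs, w)


def _deposit_trilinear(
    volume: np.ndarray, zs: np.ndarray, ys: np.ndarray, xs: np.ndarray, weights: np.ndarray
) -> None:
    z0 = np.floor(zs).astype(int)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    fz, fy, fx = zs - z0, ys - y0, xs - x0
    for dz, wz in ((0, 1 - fz), (1, fz)):
        for dy, wy in ((0, 1 - fy), (1, fy)):
            for dx, wx in ((0, 1 - fx), (1, fx)):
                np.add.at(
                    volume,
                    (z0 + dz, y0 + dy, x0 + dx),
                    weights * wz * wy * wx,
                )


def simulate_cylinder_image(spec: CylinderSpec, margin_sigmas: float = 4.0) -> ImageVolume:
    """Render stacked rings and convolve with the focal-volume Gaussian.

    Returns the PSF-convolved volume on the isotropic ``grid_pitch`` grid.
    The field of view is sized so every ring plus ``margin_sigmas`` PSF
    standard deviations fits inside.
    """
    p = spec.grid_pitch
    sig_xy = spec.psf.sigma_lateral
    sig_z = spec.psf.sigma_axial
    r = spec.diameter / 2.0

    half_x = r + margin_sigmas * sig_xy + 2 * p
    half_z = r + margin_sigmas * sig_z + 2 * p
    half_y = (spec.n_rings - 1) * spec.ring_spacing / 2.0 + margin_sigmas * sig_xy + 2 * p
    if spec.fin1_blob is not None:
        bx, by, bz, _, bsig = spec.fin1_blob
        half_x = max(half_x, abs(bx) + 4 * bsig)
        half_y = max(half_y, abs(by) + 4 * bsig)
        half_z = max(half_z, abs(bz) + 4 * bsig)

    nx = 2 * int(math.ceil(half_x / p)) + 1
    ny = 2 * int(math.ceil(half_y / p)) + 1
    nz = 2 * int(math.ceil(half_z / p)) + 1
    volume = np.zeros((nz, ny, nx))
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0

    y_offsets = (np.arange(spec.n_rings) - (spec.n_rings - 1) / 2.0) * spec.ring_spacing
    for dy in y_offsets:
        if r > 0:
            _deposit_ring(volume, (cz, cy + dy / p, cx), r / p)
        else:
            _deposit_trilinear(
                volume,
                np.array([cz]),
                np.array([cy + dy / p]),
                np.array([cx]),
                np.array([1.0]),
            )

    kernel = render_psf(spec.psf, pitch_xy=p, pitch_z=p, truncate_sigmas=margin_sigmas)
    blurred = fftconvolve(volume, kernel.voxels, mode="same")

    if spec.fin1_blob is not None:
        bx, by, bz, amp, bsig = spec.fin1_blob
        zc = (np.arange(nz) - cz) * p
        yc = (np.arange(ny) - cy) * p
        xc = (np.arange(nx) - cx) * p
        blurred = blurred + amp * (
            np.exp(-0.5 * ((zc - bz) / bsig) ** 2)[:, None, None]
            * np.exp(-0.5 * ((yc - by) / bsig) ** 2)[None, :, None]
            * np.exp(-0.5 * ((xc - bx) / bsig) ** 2)[None, None, :]
        )

    return ImageVolume(np.clip(blurred, 0.0, None), pitch_xy=p, pitch_z=p, channel="cylinder")


# ---------------------------------------------------------------------------
# Calibrated counting spots

#: Default camera noise for counting-mode spot images: EMCCD-like gain of
#: 2 camera units per photon plus 20-unit read noise.
DEFAULT_SPOT_NOISE = NoiseModel(gain=2.0, read_noise_sd=20.0)


def _json_ready(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _json_ready(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    return obj


@dataclass(frozen=True)
class ClusterSpotTruth:
    """Ground truth for one synthetic kinetochore-cluster spot image."""

    copies_per_kinetochore: float
    n_kinetochores: int
    single_gfp_amplitude: float
    sd_xy: float = 120.0
    sd_z: float = 350.0
    background: float = 100.0
    noise: NoiseModel = NOISELESS
    seed: int = 0

    @property
    def amplitude(self) -> float:
        return self.copies_per_kinetochore * self.n_kinetochores * self.single_gfp_amplitude

    def to_json(self) -> str:
        return json.dumps(_json_ready(self), indent=2, sort_keys=True)


def simulate_cluster_spot(
    copies_per_kinetochore: float,
    n_kinetochores: int,
    calib: CalibrationStandard,
    sd_xy: float = 120.0,
    sd_z: float = 350.0,
    background: float = 100.0,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    shape: tuple[int, int, int] = (9, 21, 21),
    pitch_xy: float = 140.0,
    pitch_z: float = 300.0,
) -> tuple[ImageVolume, ClusterSpotTruth]:
    """Render one diffraction-limited cluster spot with camera noise.

    The spot is a 3D Gaussian whose peak amplitude above background equals
    ``copies_per_kinetochore * n_kinetochores`` times the single-GFP
    amplitude, i.e. brightness is strictly linear in copy number.
    """
    if copies_per_kinetochore < 0:
        raise ValueError("copy number must be >= 0")
    truth = ClusterSpotTruth(
        copies_per_kinetochore=copies_per_kinetochore,
        n_kinetochores=n_kinetochores,
        single_gfp_amplitude=calib.single_gfp_amplitude,
        sd_xy=sd_xy,
        sd_z=sd_z,
        background=background,
        noise=noise,
        seed=seed,
    )
    nz, ny, nx = shape
    z = (np.arange(nz) - (nz - 1) / 2.0) * pitch_z
    y = (np.arange(ny) - (ny - 1) / 2.0) * pitch_xy
    x = (np.arange(nx) - (nx - 1) / 2.0) * pitch_xy
    clean = background + truth.amplitude * (
        np.exp(-0.5 * (z / sd_z) ** 2)[:, None, None]
        * np.exp(-0.5 * (y / sd_xy) ** 2)[None, :, None]
        * np.exp(-0.5 * (x / sd_xy) ** 2)[None, None, :]
    )
    rng = np.random.default_rng(seed)
    noisy = noise.apply(clean, rng)
    return ImageVolume(noisy, pitch_xy=pitch_xy, pitch_z=pitch_z, channel="GFP"), truth


# ---------------------------------------------------------------------------
# Two-channel particle populations for single-particle averaging


@dataclass(frozen=True)
class PopulationTruth:
    """Parameters of a synthetic two-channel particle population.

    ``cluster_axial_fwhm`` is the extent (FWHM, nm) of the kinetochore
    cluster along the spindle axis as it appears in the image — the
    quantity the averaging pipeline is asked to recover.  Clusters sit
    ``cluster_offset`` nm from their spindle pole toward the midzone.
    Fiducial (pole) spots are rendered at the focal-volume width.

    Each cluster is built from ``n_kinetochores`` discrete
    diffraction-limited spots whose positions are drawn per image from the
    cluster envelope (16 kinetochores per half spindle in budding yeast);
    this sampling scatter, not camera noise, dominates the residual
    structure of population averages, as it does in real reconstructions.
    ``n_kinetochores = 0`` renders the smooth envelope instead — the
    infinite-kinetochore, noise-free limit used by deterministic tests.
    """

    n_images: int = 24
    phase: str = "metaphase"
    cluster_axial_fwhm: float = 468.2
    cluster_radial_fwhm: float = 300.0
    cluster_offset: float = 150.0
    n_kinetochores: int = 16
    separation_range: tuple[float, float] | None = None
    fiducial_amplitude: float = 2000.0
    cluster_amplitude: float = 1500.0
    background: float = 50.0
    psf: PSFModel = SIM_PSF
    noise: NoiseModel = NoiseModel(gain=1.0, read_noise_sd=10.0)
    pitch_xy: float = 40.0
    pitch_z: float = 125.0
    shape: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.phase not in ("metaphase", "anaphase"):
            raise ValueError("phase must be 'metaphase' or 'anaphase'")

    @property
    def separations(self) -> tuple[float, float]:
        if self.separation_range is not None:
            return self.separation_range
        return (1500.0, 1900.0) if self.phase == "metaphase" else (2100.0, 3200.0)

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        """Field of view sized so rotated half-spindle windows stay inside."""
        if self.shape is not None:
            return self.shape
        # pole at sep/2 + jitter, plus the diagonal of a 640 nm half-window
        half_nm = self.separations[1] / 2.0 + 60.0 + math.sqrt(2.0) * 640.0 + 120.0
        half_px = int(math.ceil(half_nm / self.pitch_xy))
        return (13, 2 * half_px + 1, 2 * half_px + 1)

    def to_json(self) -> str:
        return json.dumps(_json_ready(self), indent=2, sort_keys=True)


@dataclass
class SyntheticParticle:
    """One simulated cell: fiducial channel, protein channel, and truth.

    ``along_offsets`` holds the drawn kinetochore positions along the
    spindle axis relative to each cluster centre (mother then daughter),
    empty when the smooth envelope was rendered.
    """

    gfp: ImageVolume
    cherry: ImageVolume
    mother_xyz: tuple[float, float, float]
    daughter_xyz: tuple[float, float, float]
    separation: float
    angle: float
    along_offsets: np.ndarray = field(default_factory=lambda: np.empty(0))


def realized_axial_fwhm(particles: Sequence[SyntheticParticle], truth: PopulationTruth) -> float:
    """Image-level axial cluster FWHM realized by a finite population.

    A finite draw of kinetochore positions has a sample spread that
    fluctuates around the envelope parameter; the extent actually present
    in the images is the pooled position variance plus the spot width.
    Falls back to the ensemble parameter for smooth-envelope populations.
    """
    pooled = np.concatenate([p.along_offsets for p in particles])
    if pooled.size == 0:
        return truth.cluster_axial_fwhm
    var_obs = float(np.var(pooled)) + truth.psf.sigma_lateral**2
    return 2.0 * math.sqrt(2.0 * math.log(2.0)) * math.sqrt(var_obs)


def _anisotropic_blob(
    shape: tuple[int, int, int],
    pitch_xy: float,
    pitch_z: float,
    center_xyz: tuple[float, float, float],
    axis_xy: tuple[float, float],
    sigma_along: float,
    sigma_perp: float,
    sigma_z: float,
    amplitude: float,
) -> np.ndarray:
    """Gaussian blob elongated along an in-plane axis, point-sampled."""
    nz, ny, nx = shape
    zc = np.arange(nz) * pitch_z - center_xyz[2]
    yc = np.arange(ny) * pitch_xy - center_xyz[1]
    xc = np.arange(nx) * pitch_xy - center_xyz[0]
    X, Y = np.meshgrid(xc, yc, indexing="xy")
    ux, uy = axis_xy
    along = X * ux + Y * uy
    perp = -X * uy + Y * ux
    plane = np.exp(-0.5 * (along / sigma_along) ** 2 - 0.5 * (perp / sigma_perp) ** 2)
    gz = np.exp(-0.5 * (zc / sigma_z) ** 2)
    return amplitude * gz[:, None, None] * plane[None, :, :]


def _deposit_spot(
    arr: np.ndarray,
    pitch_xy: float,
    pitch_z: float,
    center_xyz: tuple[float, float, float],
    sigma_xy: float,
    sigma_z: float,
    amplitude: float,
) -> None:
    """Add one point-sampled 3D Gaussian spot on a local crop."""
    nz, ny, nx = arr.shape
    cxp, cyp, czp = center_xyz[0] / pitch_xy, center_xyz[1] / pitch_xy, center_xyz[2] / pitch_z
    hx = int(math.ceil(4 * sigma_xy / pitch_xy)) + 1
    hz = int(math.ceil(4 * sigma_z / pitch_z)) + 1
    x_lo, x_hi = max(int(cxp) - hx, 0), min(int(cxp) + hx + 2, nx)
    y_lo, y_hi = max(int(cyp) - hx, 0), min(int(cyp) + hx + 2, ny)
    z_lo, z_hi = max(int(czp) - hz, 0), min(int(czp) + hz + 2, nz)
    if x_lo >= x_hi or y_lo >= y_hi or z_lo >= z_hi:
        return
    xs = np.arange(x_lo, x_hi) * pitch_xy - center_xyz[0]
    ys = np.arange(y_lo, y_hi) * pitch_xy - center_xyz[1]
    zs = np.arange(z_lo, z_hi) * pitch_z - center_xyz[2]
    g = (
        np.exp(-0.5 * (zs / sigma_z) ** 2)[:, None, None]
        * np.exp(-0.5 * (ys / sigma_xy) ** 2)[None, :, None]
        * np.exp(-0.5 * (xs / sigma_xy) ** 2)[None, None, :]
    )
    arr[z_lo:z_hi, y_lo:y_hi, x_lo:x_hi] += amplitude * g


def simulate_particle_population(truth: PopulationTruth) -> list[SyntheticParticle]:
    """Generate a population of two-channel spindle images.

    Each image holds two fiducial spots (mCherry channel) at a
    phase-consistent separation along a randomly oriented in-plane spindle
    axis, and two protein clusters (GFP channel) offset from the poles
    toward the midzone with the specified axial extent.  Clusters are
    sums of discrete kinetochore spots unless ``n_kinetochores`` is 0;
    the envelope from which positions are drawn is deconvolved for the
    spot width so the image-level cluster extent matches the requested
    FWHM in expectation.
    """
    rng = np.random.default_rng(truth.seed)
    shape = truth.volume_shape
    nz, ny, nx = shape
    center = (
        (nx - 1) / 2.0 * truth.pitch_xy,
        (ny - 1) / 2.0 * truth.pitch_xy,
        (nz - 1) / 2.0 * truth.pitch_z,
    )
    sig_ax = fwhm_to_sigma(truth.cluster_axial_fwhm)
    sig_rad = fwhm_to_sigma(truth.cluster_radial_fwhm)
    lo, hi = truth.separations
    particles: list[SyntheticParticle] = []
    for _ in range(truth.n_images):
        sep = rng.uniform(lo, hi)
        angle = rng.uniform(0.0, 2.0 * np.pi)
        jitter = rng.uniform(-60.0, 60.0, size=2)
        ux, uy = math.cos(angle), math.sin(angle)
        cx, cy = center[0] + jitter[0], center[1] + jitter[1]
        cz = center[2]
        mother = (cx - ux * sep / 2, cy - uy * sep / 2, cz)
        daughter = (cx + ux * sep / 2, cy + uy * sep / 2, cz)

        cherry = np.full(shape, truth.background, dtype=float)
        for pole in (mother, daughter):
            cherry += _anisotropic_blob(
                shape,
                truth.pitch_xy,
                truth.pitch_z,
                pole,
                (ux, uy),
                truth.psf.sigma_lateral,
                truth.psf.sigma_lateral,
                truth.psf.sigma_axial,
                truth.fiducial_amplitude,
            )
        gfp = np.full(shape, truth.background, dtype=float)
        spot_lat = truth.psf.sigma_lateral
        spot_ax = truth.psf.sigma_axial
        env_along = math.sqrt(max(sig_ax**2 - spot_lat**2, 0.0))
        env_perp = math.sqrt(max(sig_rad**2 - spot_lat**2, 0.0))
        env_z = math.sqrt(max(sig_rad**2 - spot_ax**2, 0.0))
        along_record = []
        for pole, sign in ((mother, +1.0), (daughter, -1.0)):
            cc = (
                pole[0] + sign * ux * truth.cluster_offset,
                pole[1] + sign * uy * truth.cluster_offset,
                pole[2],
            )
            if truth.n_kinetochores == 0:
                gfp += _anisotropic_blob(
                    shape,
                    truth.pitch_xy,
                    truth.pitch_z,
                    cc,
                    (ux, uy),
                    sig_ax,
                    sig_rad,
                    sig_rad,
                    truth.cluster_amplitude,
                )
                continue
            # kinetochore positions in the spindle frame (along, perp, z)
            along = rng.normal(0.0, env_along, truth.n_kinetochores)
            perp = rng.normal(0.0, env_perp, truth.n_kinetochores)
            dz = rng.normal(0.0, env_z, truth.n_kinetochores)
            along_record.append(sign * along)
            amp = truth.cluster_amplitude / truth.n_kinetochores
            for a, b, c in zip(along, perp, dz):
                pos = (cc[0] + a * ux - b * uy, cc[1] + a * uy + b * ux, cc[2] + c)
                _deposit_spot(
                    gfp, truth.pitch_xy, truth.pitch_z, pos, spot_lat, spot_ax, amp
                )
        particles.append(
            SyntheticParticle(
                gfp=ImageVolume(
                    truth.noise.apply(gfp, rng),
                    pitch_xy=truth.pitch_xy,
                    pitch_z=truth.pitch_z,
                    channel="GFP",
                ),
                cherry=ImageVolume(
                    truth.noise.apply(cherry, rng),
                    pitch_xy=truth.pitch_xy,
                    pitch_z=truth.pitch_z,
                    channel="mCherry",
                ),
                mother_xyz=mother,
                daughter_xyz=daughter,
                separation=sep,
                angle=angle,
                along_offsets=(
                    np.concatenate(along_record) if along_record else np.empty(0)
                ),
            )
        )
    return particles


# ---------------------------------------------------------------------------
# FRAP time courses


@dataclass(frozen=True)
class FrapSeriesTruth:
    """Ground truth of a step-bleach recovery curve.

    The post-bleach model is
    ``I(t) = prebleach * (post + (plateau - post) * (1 - exp(-t/tau)))``
    with t measured from the bleach frame; prebleach frames sit at the
    prebleach level.
    """

    prebleach: float = 1000.0
    post_fraction: float = 0.2
    plateau_fraction: float = 0.6
    tau_min: float = 8.0
    times_min: tuple[float, ...] = tuple(float(t) for t in range(0, 62, 2))
    n_prebleach: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.post_fraction <= self.plateau_fraction <= 1.0):
            raise ValueError("need 0 <= post fraction <= plateau fraction <= 1")
        t = np.asarray(self.times_min)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")

    def clean_trace(self) -> np.ndarray:
        t = np.asarray(self.times_min, dtype=float)
        t_bleach = t[self.n_prebleach]
        dt = t - t_bleach
        if self.tau_min > 0:
            rec = 1.0 - np.exp(-np.maximum(dt, 0.0) / self.tau_min)
        else:
            rec = (dt >= 0).astype(float)
        post = self.post_fraction + (self.plateau_fraction - self.post_fraction) * rec
        trace = np.where(dt < 0, 1.0, post)
        return self.prebleach * trace

    def to_json(self) -> str:
        return json.dumps(_json_ready(self), indent=2, sort_keys=True)


def simulate_frap_series(
    truth: FrapSeriesTruth, noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Simulate mother and daughter cluster intensity traces.

    Returns a table with columns ``time_min``, ``mother``, ``daughter``
    and ``event`` (1 on the first post-bleach frame, else 0).  Both
    clusters follow the same recovery model with independent additive
    Gaussian noise of SD ``noise_sd`` (camera units).
    """
    rng = np.random.default_rng(seed)
    clean = truth.clean_trace()
    mother = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean.copy()
    daughter = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean.copy()
    event = np.zeros(len(clean), dtype=int)
    event[truth.n_prebleach] = 1
    return pd.DataFrame(
        {
            "time_min": np.asarray(truth.times_min, dtype=float),
            "mother": mother,
            "daughter": daughter,
            "event": event,
        }
    )
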