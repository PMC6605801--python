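"""Gaussian spot fitting and FCS-calibrated molecule counting.

The brightness of a clustered-kinetochore spot is quantified by fitting a
symmetric 2D Gaussian to the maximum-intensity z slice, filtering out
spots too large to be diffraction-limited (fitted SD below 245 nm is
required), and converting the fitted amplitude to GFP copy numbers via
the single-molecule brightness predicted from an FCS-calibrated
cytosolic-GFP standard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core import CalibrationStandard, ImageVolume, KINETOCHORES_PER_CLUSTER

#: Size cutoff (nm) separating diffraction-limited clusters from
#: declustered spots; 1.75 pixels at the default 140 nm pitch.
SD_MAX_NM: float = 245.0


@dataclass
class SpotFit:
    """Parameters of one fitted fluorescent spot.

    ``center_xyz`` is in nm; ``amplitude`` is the Gaussian peak above the
    fitted constant ``offset`` (camera intensity units); ``sd`` is the
    lateral Gaussian SD in nm.
    """

    center_xyz: tuple[float, float, float]
    amplitude: float
    sd: float
    offset: float
    rss: float
    converged: bool
    z_index: int = 0

    @property
    def sd_pixels(self) -> float:
        return self.sd


def _gauss2d(params: np.ndarray, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    amp, x0, y0, sd, off = params
    return off + amp * np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2.0 * sd**2))


def fit_gaussian_spot(
    image: ImageVolume,
    init_xyz: tuple[float, float, float],
    window_px: int = 7,
    sd_bounds_px: tuple[float, float] = (0.5, 5.0),
) -> SpotFit:
    """Fit a symmetric 2D Gaussian to the brightest z slice of a spot.

    The z slice is chosen as the one with the highest intensity inside a
    small lateral window around ``init_xyz`` (x, y, z in nm); the fit has
    five free parameters (amplitude, x, y, lateral SD, constant offset)
    solved by bounded nonlinear least squares.  A flat or non-converging
    spot is returned with ``converged = False``.
    """
    v = image.voxels
    nz, ny, nx = v.shape
    iz, iy, ix = (int(round(c)) for c in image.nm_to_voxel(init_xyz))
    if not (0 <= iz < nz and 0 <= iy < ny and 0 <= ix < nx):
        raise ValueError("initial guess lies outside the image")

    y_lo, y_hi = max(iy - window_px, 0), min(iy + window_px + 1, ny)
    x_lo, x_hi = max(ix - window_px, 0), min(ix + window_px + 1, nx)
    local = v[:, y_lo:y_hi, x_lo:x_hi]
    z_best = int(np.argmax(local.max(axis=(1, 2))))
    patch = v[z_best, y_lo:y_hi, x_lo:x_hi].astype(float)

    Y, X = np.mgrid[y_lo:y_hi, x_lo:x_hi].astype(float)
    amp0 = float(patch.max() - np.median(patch))
    off0 = float(np.median(patch))
    p0 = np.array([max(amp0, 1e-6), float(ix), float(iy), 1.0, off0])
    lo = np.array([0.0, x_lo, y_lo, sd_bounds_px[0], -np.inf])
    hi = np.array([np.inf, x_hi - 1, y_hi - 1, sd_bounds_px[1], np.inf])

    try:
        res = optimize.least_squares(
            lambda p: (_gauss2d(p, X, Y) - patch).ravel(), p0, bounds=(lo, hi), xtol=1e-12
        )
        amp, x0, y0, sd_px, off = res.x
        rss = float(2.0 * res.cost)
        converged = bool(res.success) and amp > 0 and np.ptp(patch) > 0
    except ValueError:
        amp, x0, y0, sd_px, off, rss, converged = 0.0, ix, iy, 1.0, off0, float("inf"), False

    return SpotFit(
        center_xyz=(x0 * image.pitch_xy, y0 * image.pitch_xy, z_best * image.pitch_z),
        amplitude=float(amp),
        sd=float(sd_px * image.pitch_xy),
        offset=float(off),
        rss=rss,
        converged=converged,
        z_index=z_best,
    )


def filter_spots_by_size(spots: Sequence[SpotFit], sd_max: float = SD_MAX_NM) -> list[SpotFit]:
    """Keep spots whose fitted lateral SD is strictly below ``sd_max`` nm.

    The strict inequality removes declustered (non-diffraction-limited)
    spots; input order is preserved.
    """
    return [s for s in spots if s.sd < sd_max]


def apply_power_scaling(amplitude: float, calib: CalibrationStandard) -> float:
    """Rescale an amplitude measured at reduced laser power.

    Images acquired at a fraction of the calibration power are multiplied
    by the power ratio before comparison with the single-GFP standard.
    """
    return amplitude * calib.power_ratio


def copies_from_amplitude(
    amplitude: float,
    calib: CalibrationStandard,
    n_kinetochores: int = KINETOCHORES_PER_CLUSTER,
) -> tuple[float, float]:
    """Convert a fitted cluster amplitude to GFP copy numbers.

    Returns ``(copies_total, copies_per_kinetochore)`` where the total is
    the power-scaled amplitude divided by the predicted single-GFP
    amplitude, and the per-kinetochore value divides by the number of
    kinetochores in the cluster (16 for budding yeast).
    """
    if n_kinetochores < 1:
        raise ValueError("n_kinetochores must be >= 1")
    total = apply_power_scaling(amplitude, calib) / calib.single_gfp_amplitude
    return total, total / n_kinetochores


def normalized_intensity(amplitude: float, divisor: int = 1000) -> float:
    """Scale a camera-unit amplitude into the 0–10 reporting range."""
    if divisor not in (1000, 10000):
        raise ValueError("divisor must be 1000 or 10000")
    return amplitude / divisor


@dataclass(frozen=True)
class ClusterMeasurement:
    """One quantified kinetochore cluster."""

    cell_id: str
    phase: str
    amplitude: float
    sd: float
    normalized: float
    copies_total: float
    copies_per_kt: float


@dataclass(frozen=True)
class RatioEstimate:
    """Anaphase/G1 intensity ratio with first-order propagated error."""

    ratio: float
    se: float
    n_numerator: int
    n_denominator: int
    t_statistic: float
    p_value: float


def _values(measurements: Sequence) -> np.ndarray:
    out = []
    for m in measurements:
        out.append(m.normalized if hasattr(m, "normalized") else float(m))
    return np.asarray(out, dtype=float)


def anaphase_g1_ratio(
    anaphase: Sequence, g1: Sequence
) -> RatioEstimate:
    """Ratio of mean anaphase to mean G1 intensity with propagated SE.

    Accepts ``ClusterMeasurement`` sequences or plain numeric sequences.
    The standard error follows first-order propagation for a quotient of
    independent means: SE = ratio * sqrt((SE_A/mean_A)^2 + (SE_G/mean_G)^2).
    A Welch two-tailed t test between the groups is reported alongside.
    """
    a = _values(anaphase)
    g = _values(g1)
    if len(a) == 0 or len(g) == 0:
        raise ValueError("both groups must be non-empty")
    mean_a, mean_g = a.mean(), g.mean()
    if mean_g == 0:
        raise ValueError("G1 mean intensity is zero; ratio undefined")
    se_a = a.std(ddof=1) / math.sqrt(len(a)) if len(a) > 1 else 0.0
    se_g = g.std(ddof=1) / math.sqrt(len(g)) if len(g) > 1 else 0.0
    ratio = mean_a / mean_g
    se = abs(ratio) * math.sqrt((se_a / mean_a) ** 2 + (se_g / mean_g) ** 2)
    if len(a) > 1 and len(g) > 1 and (a.std(ddof=1) > 0 or g.std(ddof=1) > 0):
        t_stat, p_val = stats.ttest_ind(a, g, equal_var=False)
    else:
        t_stat, p_val = 0.0, 1.0
    return RatioEstimate(
        ratio=float(ratio),
        se=float(se),
        n_numerator=len(a),
        n_denominator=len(g),
        t_statistic=float(t_stat),
        p_value=float(p_val),
    )


def cluster_separation(spot_a: SpotFit, spot_b: SpotFit) -> float:
    """Euclidean distance (nm) between two fitted spot centres."""
    if not (spot_a.converged and spot_b.converged):
        raise ValueError("both spots must have converged fits")
    da = np.asarray(spot_a.center_xyz) - np.asarray(spot_b.center_xyz)
    return float(np.linalg.norm(da))
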