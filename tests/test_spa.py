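import math

import numpy as np
import pytest

from ktquant.core import NOISELESS, ImageVolume, PSFModel
from ktquant.simulate import PopulationTruth, simulate_particle_population
from ktquant.spa import (
    AlignedParticle,
    FiducialPair,
    SpaImage,
    average_particles,
    bootstrap_profile_se,
    classify_phase,
    contour_75,
    fiducial_corrected_distance,
    fit_fiducial_pair,
    mc_parameter_errors,
    realign_particle,
    vertical_profile_fit,
    _gauss1d,
)

PITCH_XY = 40.0
PITCH_Z = 125.0


def two_spot_volume(mother_xyz, daughter_xyz, shape=(13, 101, 101), amp=2000.0, background=50.0):
    """Render two focal-volume-sized Gaussian spots at given nm positions."""
    psf = PSFModel(119.0, 272.0)
    nz, ny, nx = shape
    vol = np.full(shape, background)
    z = np.arange(nz) * PITCH_Z
    y = np.arange(ny) * PITCH_XY
    x = np.arange(nx) * PITCH_XY
    for cx, cy, cz in (mother_xyz, daughter_xyz):
        vol += amp * (
            np.exp(-0.5 * ((z - cz) / psf.sigma_axial) ** 2)[:, None, None]
            * np.exp(-0.5 * ((y - cy) / psf.sigma_lateral) ** 2)[None, :, None]
            * np.exp(-0.5 * ((x - cx) / psf.sigma_lateral) ** 2)[None, None, :]
        )
    return ImageVolume(vol, pitch_xy=PITCH_XY, pitch_z=PITCH_Z, channel="mCherry")


CENTER = (50 * PITCH_XY, 50 * PITCH_XY, 6 * PITCH_Z)


class TestFiducialPair:
    def test_noiseless_pair_recovers_separation(self):
        m = (CENTER[0] - 750.0, CENTER[1], CENTER[2])
        d = (CENTER[0] + 750.0, CENTER[1], CENTER[2])
        vol = two_spot_volume(m, d)
        pair = fit_fiducial_pair(vol, m, d)
        assert pair.spindle_length_nm == pytest.approx(1500.0, abs=5.0)

    def test_swapped_guesses_give_same_pair(self):
        m = (CENTER[0] - 600.0, CENTER[1] + 200.0, CENTER[2])
        d = (CENTER[0] + 600.0, CENTER[1] - 200.0, CENTER[2])
        vol = two_spot_volume(m, d)
        a = fit_fiducial_pair(vol, m, d)
        b = fit_fiducial_pair(vol, d, m)
        assert np.allclose(a.mother_xyz, b.daughter_xyz, atol=1.0)
        assert np.allclose(a.daughter_xyz, b.mother_xyz, atol=1.0)

    def test_merged_components_rejected(self):
        m = (CENTER[0] - 10.0, CENTER[1], CENTER[2])
        d = (CENTER[0] + 10.0, CENTER[1], CENTER[2])
        vol = two_spot_volume(m, d)
        with pytest.raises(ValueError, match="merged"):
            fit_fiducial_pair(vol, m, d)

    def test_noisy_centers_match_center_of_mass_oracle(self):
        rng = np.random.default_rng(5)
        m = (CENTER[0] - 800.0, CENTER[1], CENTER[2])
        d = (CENTER[0] + 800.0, CENTER[1], CENTER[2])
        clean = two_spot_volume(m, d)
        noisy = ImageVolume(
            np.clip(clean.voxels + rng.normal(0, 25.0, clean.voxels.shape), 0, None),
            pitch_xy=PITCH_XY,
            pitch_z=PITCH_Z,
        )
        pair = fit_fiducial_pair(noisy, m, d)
        # oracle: background-subtracted center of mass in a half-window
        v = np.clip(noisy.voxels - np.median(noisy.voxels), 0, None)
        for fitted, init in ((pair.mother_xyz, m), (pair.daughter_xyz, d)):
            ix = int(round(init[0] / PITCH_XY))
            iy = int(round(init[1] / PITCH_XY))
            win = v[:, iy - 8 : iy + 9, ix - 8 : ix + 9]
            zz, yy, xx = np.mgrid[0:13, iy - 8 : iy + 9, ix - 8 : ix + 9]
            com_x = (win * xx).sum() / win.sum() * PITCH_XY
            com_y = (win * yy).sum() / win.sum() * PITCH_XY
            assert abs(fitted[0] - com_x) < PITCH_XY
            assert abs(fitted[1] - com_y) < PITCH_XY


class TestClassifyPhase:
    @pytest.mark.parametrize(
        "sep_um,expected",
        [(1.2, "metaphase"), (3.5, "anaphase"), (2.0, "metaphase")],
    )
    def test_threshold_and_tie_rule(self, sep_um, expected):
        m = (0.0, 0.0, 0.0)
        d = (sep_um * 1000.0, 0.0, 0.0)
        assert classify_phase(FiducialPair(m, d)) == expected

    def test_partition_is_total(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sep = rng.uniform(100, 5000)
            pair = FiducialPair((0, 0, 0), (sep, 0, 0))
            assert classify_phase(pair) in ("metaphase", "anaphase")


class TestRealign:
    def test_axis_already_on_y_preserves_fiducial_centering(self):
        m = (CENTER[0], CENTER[1] - 750.0, CENTER[2])
        d = (CENTER[0], CENTER[1] + 750.0, CENTER[2])
        vol = two_spot_volume(m, d)
        mother, daughter = realign_particle(vol, FiducialPair(m, d))
        for part in (mother, daughter):
            v = part.volume.voxels
            ny, nx = v.shape[1:]
            iy, ix = np.unravel_index(np.argmax(v[(v.shape[0] - 1) // 2]), (ny, nx))
            assert abs(iy - (ny - 1) / 2) <= 0.5
            assert abs(ix - (nx - 1) / 2) <= 0.5

    def test_rotated_axis_centers_fiducials_within_half_pixel(self):
        theta = math.radians(30.0)
        ux, uy = math.cos(theta), math.sin(theta)
        m = (CENTER[0] - 750 * ux, CENTER[1] - 750 * uy, CENTER[2])
        d = (CENTER[0] + 750 * ux, CENTER[1] + 750 * uy, CENTER[2])
        vol = two_spot_volume(m, d)
        for part in realign_particle(vol, FiducialPair(m, d)):
            v = part.volume.voxels
            proj = v[(v.shape[0] - 1) // 2]
            # subpixel peak via center of mass of the top 10% region
            w = np.clip(proj - 0.1 * proj.max(), 0, None)
            yy, xx = np.mgrid[0 : proj.shape[0], 0 : proj.shape[1]]
            cy = (w * yy).sum() / w.sum()
            cx = (w * xx).sum() / w.sum()
            assert abs(cy - (proj.shape[0] - 1) / 2) < 0.5
            assert abs(cx - (proj.shape[1] - 1) / 2) < 0.5

    def test_symmetric_cell_halves_match_after_flip(self):
        m = (CENTER[0], CENTER[1] - 600.0, CENTER[2])
        d = (CENTER[0], CENTER[1] + 600.0, CENTER[2])
        vol = two_spot_volume(m, d)
        mother, daughter = realign_particle(vol, FiducialPair(m, d))
        assert daughter.flipped and not mother.flipped
        np.testing.assert_allclose(
            mother.volume.voxels, daughter.volume.voxels, rtol=1e-7, atol=1e-7
        )

    def test_global_rotation_invariance(self):
        """Rotating the input volume by an exact quarter turn must leave the
        aligned sub-images unchanged up to interpolation error."""
        theta = math.radians(20.0)
        ux, uy = math.cos(theta), math.sin(theta)
        m = (CENTER[0] - 700 * ux, CENTER[1] - 700 * uy, CENTER[2])
        d = (CENTER[0] + 700 * ux, CENTER[1] + 700 * uy, CENTER[2])
        vol = two_spot_volume(m, d)
        mother_a, _ = realign_particle(vol, FiducialPair(m, d))

        rot = ImageVolume(
            np.rot90(vol.voxels, k=1, axes=(1, 2)).copy(),
            pitch_xy=PITCH_XY,
            pitch_z=PITCH_Z,
        )
        # rot90 over (y, x): new_y = (nx-1) - x_old, new_x = y_old
        nx = vol.voxels.shape[2]

        def rot_xyz(p):
            return (p[1], (nx - 1) * PITCH_XY - p[0], p[2])

        mother_b, _ = realign_particle(rot, FiducialPair(rot_xyz(m), rot_xyz(d)))
        a, b = mother_a.volume.voxels, mother_b.volume.voxels
        assert np.max(np.abs(a - b)) / a.max() < 0.02

    def test_clipped_window_rejected(self):
        m = (200.0, CENTER[1], CENTER[2])  # pole close to the volume edge
        d = (200.0 + 2000.0, CENTER[1], CENTER[2])
        vol = two_spot_volume(m, d)
        with pytest.raises(ValueError, match="clipped"):
            realign_particle(vol, FiducialPair(m, d))


def make_particle(image2d, nz=13):
    vol = np.repeat(image2d[None, :, :], nz, axis=0)
    return AlignedParticle(
        volume=ImageVolume(vol, pitch_xy=PITCH_XY, pitch_z=PITCH_Z),
        side="mother",
        flipped=False,
        valid_fraction=1.0,
    )


def gaussian_patch(n=33, sd_px=3.0, center_offset=(0.0, 0.0)):
    c = (n - 1) / 2
    y, x = np.mgrid[0:n, 0:n].astype(float)
    return np.exp(
        -((y - c - center_offset[0]) ** 2 + (x - c - center_offset[1]) ** 2) / (2 * sd_px**2)
    )


class TestAverage:
    def test_mirror_average_is_exactly_symmetric(self):
        rng = np.random.default_rng(3)
        particles = [make_particle(rng.random((33, 33))) for _ in range(4)]
        spa = average_particles(particles)
        np.testing.assert_array_equal(spa.image, spa.image[:, ::-1])

    def test_n_copies_equal_single(self):
        patch = gaussian_patch()
        one = average_particles([make_particle(patch)])
        many = average_particles([make_particle(patch.copy()) for _ in range(5)])
        np.testing.assert_allclose(one.image, many.image, rtol=1e-12)

    def test_symmetric_particle_upscale_idempotence(self):
        """For a mirror-symmetric particle the output equals its own
        projection, upscaled; mirror averaging changes nothing."""
        patch = gaussian_patch()
        plain = average_particles([make_particle(patch)], mirror=False)
        mirrored = average_particles([make_particle(patch)], mirror=True)
        np.testing.assert_allclose(plain.image, mirrored.image, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        a = make_particle(gaussian_patch(33))
        b = make_particle(gaussian_patch(31))
        with pytest.raises(ValueError, match="shapes"):
            average_particles([a, b])

    def test_pixel_coordinates_follow_upscale(self):
        spa = average_particles([make_particle(gaussian_patch())], upscale=8)
        assert spa.pixel_nm == pytest.approx(PITCH_XY / 8)
        # fiducial (grid centre) keeps coordinate zero
        assert spa.y_nm[(len(spa.y_nm) - 1) // 2] == pytest.approx(0.0, abs=1e-9)


class TestProfileFit:
    def test_centered_blob_fits_at_fiducial(self):
        spa = average_particles([make_particle(gaussian_patch())])
        fit = vertical_profile_fit(spa, n_mc=0)
        assert fit.center_nm == pytest.approx(0.0, abs=2.0)

    def test_known_width_recovered(self):
        sd_px = 200.0 / 2.3548 / PITCH_XY  # FWHM 200 nm
        spa = average_particles([make_particle(gaussian_patch(sd_px=sd_px))])
        fit = vertical_profile_fit(spa, n_mc=0)
        assert fit.fwhm_nm == pytest.approx(200.0, abs=10.0)

    def test_off_center_blob_center_sign(self):
        # blob displaced toward larger y (spindle side) -> positive center
        spa = average_particles([make_particle(gaussian_patch(center_offset=(4.0, 0.0)))])
        fit = vertical_profile_fit(spa, n_mc=0)
        assert fit.center_nm == pytest.approx(4.0 * PITCH_XY, abs=5.0)


class TestMonteCarloErrors:
    def setup_method(self):
        self.x = np.linspace(-500, 500, 41)
        self.params = np.array([1.0, 0.0, 120.0, 0.05])

    def test_zero_residuals_give_zero_se(self):
        ses = mc_parameter_errors(self.x, _gauss1d, self.params, np.zeros_like(self.x))
        np.testing.assert_array_equal(ses, 0.0)

    def test_se_scales_with_noise(self):
        r1 = np.full_like(self.x, 0.01)
        r1[::2] *= -1
        ses1 = mc_parameter_errors(self.x, _gauss1d, self.params, r1, n=100, seed=1)
        ses2 = mc_parameter_errors(self.x, _gauss1d, self.params, 2 * r1, n=100, seed=1)
        np.testing.assert_allclose(ses2, 2 * ses1, rtol=0.2)

    def test_matches_linearized_least_squares(self):
        """MC errors agree within a factor of two with the analytic
        sigma^2 (J^T J)^-1 covariance on a well-conditioned fit."""
        resid_sd = 0.01
        rng = np.random.default_rng(2)
        residuals = rng.normal(0, resid_sd, self.x.shape)
        ses = mc_parameter_errors(self.x, _gauss1d, self.params, residuals, n=200, seed=3)

        eps = 1e-6
        J = np.empty((len(self.x), len(self.params)))
        for j in range(len(self.params)):
            dp = self.params.copy()
            dp[j] += eps
            J[:, j] = (_gauss1d(self.x, *dp) - _gauss1d(self.x, *self.params)) / eps
        analytic = np.std(residuals) * np.sqrt(np.diag(np.linalg.inv(J.T @ J)))
        ratio = ses / analytic
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)


class TestDistances:
    def test_zero_correction_is_raw_distance(self):
        a = vertical_profile_fit(
            average_particles([make_particle(gaussian_patch(center_offset=(3.0, 0)))]), n_mc=0
        )
        b = vertical_profile_fit(
            average_particles([make_particle(gaussian_patch(center_offset=(0.0, 0)))]), n_mc=0
        )
        d = fiducial_corrected_distance(a, b)
        assert d == pytest.approx(3.0 * PITCH_XY, abs=5.0)

    def test_self_distance_is_zero(self):
        fit = vertical_profile_fit(average_particles([make_particle(gaussian_patch())]), n_mc=0)
        assert fiducial_corrected_distance(fit, fit) == pytest.approx(0.0)

    def test_channel_shift_removed_by_correction(self):
        """A systematic 30 nm inter-channel registration shift cancels when
        distances are taken relative to the shifted reference channel."""
        shift_px = 30.0 / PITCH_XY
        protein = vertical_profile_fit(
            average_particles([make_particle(gaussian_patch(center_offset=(5.0 + shift_px, 0)))]),
            n_mc=0,
        )
        reference = vertical_profile_fit(
            average_particles([make_particle(gaussian_patch(center_offset=(shift_px, 0)))]),
            n_mc=0,
        )
        d = fiducial_corrected_distance(protein, reference)
        assert d == pytest.approx(5.0 * PITCH_XY, abs=5.0)


class TestContours:
    def test_single_blob_gives_one_closed_contour(self):
        spa = average_particles([make_particle(gaussian_patch())])
        cm = contour_75(spa)
        assert len(cm.polygons) == 1
        poly = cm.polygons[0]
        np.testing.assert_allclose(poly[0], poly[-1])
        assert np.hypot(*poly.mean(axis=0)) < 10.0

    def test_two_separated_blobs_give_two_contours(self):
        patch = gaussian_patch(65, sd_px=2.0, center_offset=(-12.0, 0)) + gaussian_patch(
            65, sd_px=2.0, center_offset=(12.0, 0)
        )
        spa = average_particles([make_particle(patch)], mirror=False)
        cm = contour_75(spa)
        assert len(cm.polygons) == 2

    def test_contour_area_matches_analytic_level_set(self):
        """The 75% level set of an isotropic Gaussian of SD s encloses
        area pi * 2 ln(4/3) * s^2."""
        sd_px = 3.0
        spa = average_particles([make_particle(gaussian_patch(65, sd_px=sd_px))], mirror=False)
        cm = contour_75(spa)
        poly = cm.polygons[0]
        y, x = poly[:, 0], poly[:, 1]
        area = 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
        expected = math.pi * 2.0 * math.log(4.0 / 3.0) * (sd_px * PITCH_XY) ** 2
        assert area == pytest.approx(expected, rel=0.05)


class TestRoundTripPipeline:
    def test_alignment_residual_on_noiseless_population(self):
        truth = PopulationTruth(
            n_images=4, phase="metaphase", n_kinetochores=0, noise=NOISELESS, seed=6
        )
        for p in simulate_particle_population(truth):
            pair = fit_fiducial_pair(p.cherry, p.mother_xyz, p.daughter_xyz)
            assert abs(pair.spindle_length_nm - p.separation) < 0.5 * PITCH_XY

    def test_axial_extent_recovered_within_two_sem(self):
        """24-image metaphase population at a 350 nm axial extent: the full
        align/average/fit pipeline recovers the truth within twice the
        particle-bootstrap SEM."""
        truth = PopulationTruth(n_images=24, phase="metaphase", cluster_axial_fwhm=350.0, seed=13)
        particles = simulate_particle_population(truth)
        aligned = []
        for p in particles:
            pair = fit_fiducial_pair(p.cherry, p.mother_xyz, p.daughter_xyz)
            mother, daughter = realign_particle(p.gfp, pair)
            aligned += [mother, daughter]
        spa = average_particles(aligned)
        fit = vertical_profile_fit(spa, n_mc=0)
        _, se_w = bootstrap_profile_se(aligned, n_boot=40, seed=14)
        assert abs(fit.fwhm_nm - 350.0) <= 2 * se_w
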