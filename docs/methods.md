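# Methods

This note documents the models behind `ktquant`, the defaults and their
origins, what the synthetic data does and does not emulate, and the
numerical choices that shape the results.

## Coordinate and unit conventions

Volumes are stored `(z, y, x)` with y the spindle axis; coordinates are
voxel-centred, 0-based, and reported in nm (µm only for spindle lengths
at the CLI). The Gaussian width conversion is fixed at
FWHM = 2·√(2·ln 2)·σ ≈ 2.3548·σ. Default camera pitches are 140 nm
laterally (from the equivalence of a 245 nm SD with 1.75 pixels) and
300 nm between z slices for counting-mode imaging; the synthetic SIM
populations use 40 nm / 125 nm, typical of reconstructed
structured-illumination stacks.

## Focal volume

The microscope point-spread function is modelled as a separable 3D
Gaussian with 119 nm lateral and 272 nm axial FWHM — the widths measured
from Gaussian fits to averaged spindle-pole fiducial reconstructions.
Kernels are rendered over ±4σ and normalized to unit sum; rendering
refuses pitches above half the FWHM (aliasing). Convolution of interior
sources conserves total intensity to better than 0.1%.

## Spot quantification and calibrated counting

Cluster spots are fit on their maximum-intensity z slice with a
symmetric 2D Gaussian (amplitude, centre, lateral SD, constant offset)
by bounded least squares, SD constrained to 0.5–5 pixels and initialized
at 1 pixel with amplitude = max − median. The reported amplitude is
offset-subtracted; whether the original protocol included the local
offset is not documented, but ratios of amplitudes are insensitive to
this choice. Spots with SD ≥ 245 nm (strict inequality at the cutoff)
are discarded as declustered. Copy numbers divide the power-scaled
amplitude by the single-GFP amplitude predicted from an FCS-measured
cytosolic-GFP standard; per-kinetochore values assume 16 kinetochores
per cluster (configurable). Anaphase/G1 ratios use first-order error
propagation for a quotient of independent means,
SE = r·√((SE_A/μ_A)² + (SE_G/μ_G)²), with a Welch t test reported
alongside as a convenience.

## FRAP

Traces are divided by the prebleach frame. Percent recovery is
100·(I_end − I_post)/(1 − I_post), where I_post averages the first
`post_window` frames after the bleach (default 1) and I_end the last
`end_window` frames (default 2); window sizes are configurable because
the endpoint convention of the original protocol is not recorded. Values
outside [0, 150]% are flagged but never clamped; a bleach that fails to
drop below the prebleach level is an error. The measure is invariant
under affine intensity rescaling. Acquisition-bleaching detrending is
not applied; the synthetic series carry no acquisition bleaching.

## Single-particle averaging

Per cell, the two fiducial spots are fit simultaneously with two 3D
Gaussians (shared widths, free amplitudes and centres, constant offset)
inside a padded bounding box around the hand annotations; fits whose
centres approach within one pixel are rejected as merged. Cells are
classed metaphase/anaphase by inter-fiducial distance with a 2 µm
threshold; a tie at exactly 2 µm counts as metaphase (the published
classes are open intervals on both sides, so equality had to be assigned
to one of them).

Each volume is rigid-rotated (linear interpolation, one resampling pass)
so the inter-fiducial axis lies along +y, then split into mother and
daughter sub-images of ±640 nm laterally, each with its own fiducial at
the exact sub-image centre and the daughter flipped along y so both
spindles point toward the image bottom. Sub-images sampled more than 10%
outside the source volume are rejected. Averaging max-projects 5 z
slices around the fiducial plane, optionally normalizes each projection
to its maximum (default on), takes the pixel-wise mean over all mother
and daughter images pooled, upscales 8-fold with edge-aligned bilinear
interpolation, and averages the result with its left-right mirror — the
output is exactly mirror-symmetric by construction. Contours are drawn
after a further 4-fold bilinear upscale (32-fold total over raw pixels)
at 75% of the image maximum.

Axial profiles are the column means of the average. The Gaussian profile
fit is evaluated at the native (pre-upscale) pixel spacing: upscaled
samples are interpolants of the raw ones, and fitting them would make
residual-based errors overconfident. Cluster size along the spindle is
reported as both the fitted SD and the FWHM; FWHM is the headline
number. Inter-channel distances are taken relative to the own-channel
fiducial centre and corrected by the offset measured from a two-colour
calibration pair, which cancels systematic channel registration shifts.

Two error estimates are produced. Monte-Carlo refits (default 100) add
i.i.d. Gaussian noise at the residual SD to the best-fit model and
report the SD of each refit parameter; this quantifies fit noise for the
given average image. A bootstrap over aligned particles repeats
average + fit on resampled populations and additionally captures
particle-to-particle variability — for population averages of
finite-sample clusters the bootstrap SE is the appropriate uncertainty
for round-trip comparisons, and it is systematically larger than the
residual-MC SE (see below).

## Cylinder forward model

Kinetochore rings are circles in planes perpendicular to the spindle
axis (the published geometry: four circles, 75 nm spacing, 250 nm
diameter, 5 nm isotropic grid), deposited as sub-voxel-weighted ring
samples so the rendered image is a smooth function of the radius, then
convolved with the focal-volume Gaussian. An optional extra 3D Gaussian
emulates a pole-proximal protein signal. The lateral profile through a
ring plane is bi-lobed whenever the diameter sufficiently exceeds the
lateral PSF width; convolution pulls the lobe maxima well inside the
true radius, so the diameter is estimated by least-squares matching of
the forward profile (amplitude and offset free) over candidate
diameters. Because a one-ring x–z render reproduces the interior-ring
lateral profile of the full stack up to scale, the search uses a fast 2D
equivalent of the 3D model (cross-checked against the 3D render in the
tests). The misfit landscape over diameter is multimodal — a wide
bi-lobed template can shadow-fit a narrow profile — so the search scans
a 10 nm grid before bounded local refinement instead of relying on a
single unimodal bracket. Profiles with no interior dip are fit anyway
but flagged low-identifiability. Ring spacing along the axis is
recovered with an equal-amplitude, equal-spacing Gaussian-mixture fit of
the integrated axial profile.

## Synthetic data

The generators produce exactly the statistical structure the analysis
assumes, with every ground-truth parameter recorded and bit-identical
regeneration from (truth, seed).

*Counting spots* are 3D Gaussians (SD 120 nm lateral, 350 nm axial) on a
flat background of 100 counts, peak amplitude strictly linear in copy
number, with Poisson photon noise (default gain 2 counts/photon) and
Gaussian read noise (default SD 20 counts).

*Particle populations* place two fiducial spots at a phase-consistent
separation (metaphase 1.5–1.9 µm, anaphase 2.1–3.2 µm, uniform) along a
uniformly random in-plane axis, with ±60 nm centre jitter. Each protein
cluster is a sum of 16 discrete kinetochore spots of focal-volume size
whose positions are drawn from an anisotropic Gaussian envelope centred
150 nm from the pole toward the midzone; the envelope is deconvolved for
the spot width so the image-level cluster extent matches the requested
FWHM in expectation. Discreteness matters: it gives population averages
the residual speckle that real reconstructions show, and it makes each
population's realized extent fluctuate by a few percent around the
ensemble parameter — both effects the smooth-envelope limit
(`n_kinetochores = 0`, used by deterministic tests) lacks. Defaults for
the cluster extent follow the published wild-type Nuf2 values (468.2 nm
metaphase, 194.0 nm anaphase axial FWHM; 300 nm radial FWHM as a
representative lateral width).

*FRAP series* follow a step bleach with single-exponential recovery,
I(t) = pre·[post + (plateau − post)(1 − e^(−t/τ))], defaults post = 0.2,
plateau = 0.6, τ = 8 min, 2-min sampling over an hour, additive Gaussian
noise.

What the generators do **not** emulate: SIM reconstruction artifacts and
structured residual noise, optical aberrations and depth-dependent PSF
variation, cell autofluorescence, chromatic offsets beyond a constant
channel shift, expression-level variability, and kinetochore substructure
beyond independent Gaussian placement. Passing round trips therefore
demonstrate the correctness and calibration of the computations on data
obeying the stated model, not robustness to every pathology of real
microscopy.

## Accuracy of the SPA round trip

Three small, well-understood systematics separate the pipeline's output
from the generator parameter. (1) Each linear-interpolation resampling
pass (the rotation) adds ≈ h²/6 ≈ 267 nm² of variance at h = 40 nm
pixels — about +1 nm on a 468 nm FWHM and +4 nm on a 194 nm FWHM.
(2) Max projection over z soft-clips faint Gaussian wings into the
noise-raised floor, slightly narrowing fits. (3) A population average of
finite-sample clusters is a scale mixture of Gaussians — mildly
leptokurtic — and a Gaussian LSQ fit of such a profile reads low
relative to the moment width, by an amount that fluctuates with the
draw. Effects (1)–(3) largely offset on average but leave a
seed-dependent scatter of a few percent; the particle bootstrap SE
tracks this scatter well (verified against replicate populations in
development), which is why round-trip tests use 2 bootstrap SEs as their
tolerance while the residual-MC SE is reported for comparability with
the conventional error estimate. Problem sizes throughout (24 images per
population, 100 Monte-Carlo refits, 50 bootstrap draws, 100 counting
replicates) match the scales of the original study's reported analyses.

## Degenerate inputs and tie-breaks

Flat spot images return non-converged fits rather than raising; zero or
negative prebleach intensity, failed bleaches, merged fiducials, empty
particle lists, shape mismatches, and non-positive calibrations raise
`ValueError`. The 245 nm filter is strict (`<`); the 2 µm phase
threshold assigns equality to metaphase; diameter estimates at a search
bound or without an interior profile dip carry a low-identifiability
flag instead of failing.
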