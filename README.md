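# ktquant

Quantitative fluorescence-imaging analysis of budding-yeast kinetochore
clusters. In *S. cerevisiae* the 16 kinetochores of a half spindle gather
into one sub-diffraction spot, so questions about kinetochore composition
become questions about careful photometry and sub-resolution image
statistics. This package implements, with a fully synthetic test bed, the
four measurement modes used to study outer-kinetochore stoichiometry:

- **FCS-calibrated molecule counting** — a cluster spot's Gaussian
  amplitude `A` is converted to GFP copies via the amplitude `A₁`
  predicted for a single GFP from a fluorescence-correlation-spectroscopy
  concentration standard: `N = (A · power_ratio) / A₁`, and per
  kinetochore `n = N / 16`. Spots are accepted only when the fitted
  lateral SD is below 245 nm (1.75 pixels at 140 nm pitch), which rejects
  declustered kinetochores.
- **FRAP percent recovery** — traces normalized to the prebleach frame;
  `recovery = 100 · (I_end − I_post) / (1 − I_post)` with windowed
  endpoint averaging, plus group means/SDs and a Welch t test.
- **SPA-SIM single-particle averaging** — each two-channel SIM volume is
  registered on the axis through its two spindle-pole (Spc42) fiducials,
  split at the midpoint into mother and daughter half-spindle images,
  max-projected over five z slices, averaged, upscaled 8× with bilinear
  interpolation, and mirror-averaged. Axial profiles of the average are
  fit with single Gaussians; errors come from 100 Monte-Carlo refits at
  the residual noise level and from a bootstrap over particles.
- **Cylinder forward model** — kinetochores arranged on the surface of a
  spindle-coaxial cylinder (four rings, 75 nm apart, 250 nm diameter,
  rendered at 5 nm and convolved with the 119/272 nm FWHM focal volume)
  produce a bi-lobed cross-spindle profile; the model is inverted by
  least squares to estimate the cylinder diameter from such a profile.

All test inputs are generated by `ktquant.simulate`, which produces PSF
kernels, cylinder volumes, counting spots with Poisson + read noise,
FRAP series, and two-channel spindle populations whose clusters are
built from 16 discrete kinetochore spots with known geometry.

## Worked example

```python
from ktquant.core import CalibrationStandard, SIM_PSF
from ktquant.cylinder import estimate_diameter, forward_profile, lobe_separation
from ktquant.simulate import CylinderSpec, DEFAULT_SPOT_NOISE, simulate_cluster_spot
from ktquant.spots import copies_from_amplitude, fit_gaussian_spot

# invert the cylinder forward model at the published ring geometry
spec = CylinderSpec()                      # 4 rings, 75 nm apart, 250 nm diameter
profile = forward_profile(spec)
est = estimate_diameter(profile, SIM_PSF, n_mc=0)
print(f"lobe separation: {lobe_separation(profile):.1f} nm")
print(f"fitted cylinder diameter: {est.diameter_nm:.1f} nm")

# count GFP copies in a synthetic late-anaphase cluster
calib = CalibrationStandard(single_gfp_amplitude=150.0)
image, truth = simulate_cluster_spot(4.0, 16, calib, noise=DEFAULT_SPOT_NOISE, seed=1)
fit = fit_gaussian_spot(image, (10 * 140.0, 10 * 140.0, 4 * 300.0))
total, per_kt = copies_from_amplitude(fit.amplitude, calib)
print(f"fitted amplitude: {fit.amplitude:.0f} counts (sd {fit.sd:.0f} nm)")
print(f"copies: {total:.1f} total, {per_kt:.2f} per kinetochore")
```

prints

```
lobe separation: 180.4 nm
fitted cylinder diameter: 250.2 nm
fitted amplitude: 9603 counts (sd 120 nm)
copies: 64.0 total, 4.00 per kinetochore
```

The lobe maxima of the 250 nm cylinder sit only ~180 nm apart — PSF
convolution pulls them inward — which is exactly why the diameter is
estimated by full forward-model fitting rather than by peak-to-peak
distance. The counting example recovers the generated 4 copies per
kinetochore from a noisy image.

A command-line layer wraps the same functions:

```sh
ktq simulate frap --seed 3 --out demo/
ktq frap --series demo/frap_series.csv --out demo/recovery.csv
ktq cylinder-fit --profile profile.csv --psf 119,272 --out diameter.json
```

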