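# Methods

This note records the models phantomforge implements, the defaults it ships,
the numerical choices behind them, and what the package deliberately does not
claim to reproduce.

## Optical property models

**Collagen absorption.** Absorption of hydrated collagen is modeled as a
single exponential in wavelength, `mu_a(lambda) = A * exp(-k * lambda)` with
literature coefficients `A = 416.51 cm^-1`, `k = 0.014 nm^-1`, valid for
300–600 nm. At the 405 nm design wavelength this gives 1.44 cm^-1. The model
assumes scattering has been fully removed from the underlying transmission
measurements and that collagen hydration matches the calibration samples.

**Reduced scattering, power law.** Tissue reduced scattering follows the Mie
power law `mu_s'(lambda) = a * (lambda / lambda_ref)^-b`. The shipped
dense-breast preset uses `a = 15.12 +/- 2.24 cm^-1`, `b = 1.05 +/- 0.292`,
`lambda_ref = 600 nm` (valid 400–1300 nm), giving 22.84 cm^-1 at 405 nm.
Uncertainty is propagated to first order:
`delta_mu = (lambda/lambda_ref)^-b * sqrt(delta_a^2 + (a * ln(lambda/lambda_ref) * delta_b)^2)`,
which assumes independent errors in `a` and `b` and gives 4.28 cm^-1 at
405 nm. Evaluating a model outside its stated validity range emits a
`ValidityRangeWarning` by default and raises with `strict=True`.

**Reduced scattering, Rayleigh–Mie.** For adipose tissue a combined model
`a' * (f_Ray * (lambda/500)^-4 + (1 - f_Ray) * (lambda/500)^-b_Mie)` is also
provided (`a' = 11.2 cm^-1`, `f_Ray = 0.29`, `b_Mie = 0.089`). Together with
the adipose power law (`a = 10.6 cm^-1`, `b = 0.520`, `lambda_ref = 500 nm`)
it brackets adipose `mu_s'(405 nm)` between 11.8 and 15.6 cm^-1. The lower
bound is reported as computed (11.83 → prints as 11.8); the upper as 15.6.
`scattering_bound_interval` refuses mid-point targets that weight the
Rayleigh–Mie bound below 50% by default, an arbitrary but explicit guard
against extrapolating past the bracket.

**Exponential fitting.** `fit_exponential_absorption` fits in log space with
`numpy.polyfit` (ordinary least squares on `ln mu_a` vs `lambda`). This
weights relative rather than absolute error, which is appropriate for a
quantity spanning orders of magnitude, and requires at least three points and
strictly positive data. R² is reported in log space.

## Spectroscopy

`transmission_to_absorption` applies the Beer–Lambert inversion
`mu_a = -(1/d) * ln(%T / 100)` to the replicate-mean transmission, with the
stated assumption that the sample is scattering-free (dye solutions, not
turbid phantoms). The uncertainty convention is
`delta_mu_a = sigma / (d * mean(%T))` with `%T` and `sigma` both in percent
units; e.g. mean 10 %T with sigma 1 % over a 1 cm path gives 0.1 cm^-1.

Coverage caveat: that band is a first-order (delta-method) one-sigma interval.
It covers the true value ~68% of the time only when `sigma` is the *known*
noise standard deviation of a *single* measurement — hence the explicit
`sigma=` override. If instead the sample standard deviation of triplicates is
divided by the triplicate mean, the band is a one-sigma band on a single
replicate, not on the mean, and empirically covers ~92% of wavelengths. The
test suite checks the 68% case with known sigma on a 601-wavelength grid.

Calibration slopes (`fit_calibration`) use zero-intercept least squares
`slope = sum(c * mu) / sum(c^2)`, because zero concentration must give zero
absorption; R² is computed about zero (uncentered), consistent with the
forced intercept.

## Recipe design

- Hemoglobin: `C = MW * mu_a / (ln10 * eps)` with `MW = 64,500 g/mol` and a
  mixed oxy/deoxy molar extinction at 405 nm of 310,610.8 cm^-1 M^-1
  (70% oxygenated). 1.44 cm^-1 → 0.130 g/L.
- Mixtures: component concentrations scale a user-given ratio vector so the
  calibrated slopes sum exactly to the target, `C_i = target * r_i /
  sum_j(r_j * mu_j)`; conservation holds to 1e-12 relative.
- Intralipid: pre-correction % = `(target_mm / 1.9035)` where `target_mm` is
  the `mu_s'` target converted from cm^-1 to mm^-1; the final concentration
  divides by the 8% gelatin scatter correction 80/220 (gelatin itself
  scatters, so less intralipid is needed per unit of gel... the correction is
  empirical and only valid at 8% gelatin, so other gelatin fractions require
  an explicit correction factor). 22.84 cm^-1 → 1.20% pre, 3.30% final;
  14.53 cm^-1 → 2.1% final.
- Film dispense volume: `min(3 + 1.5 * (t - 200)/100, 7) mL` for thickness
  `t` in µm; 200 µm → 3 mL, capped at 7 mL from 467 µm up (1000 µm → 7 mL).
  The cap reflects mold capacity, not physics.
- Gelatin fraction must be ≥ 4% for the gel to set; the default is 8% to
  match the only gelatin fraction the scatter correction was measured at.

## Well-chip geometry and classification

The default chip is five concentric rings of ten wells each, well diameters
100/250/500/1000/5000 µm at ring radii 4/8/12/16/20.5 mm, angular index
clockwise from 12 o'clock, one blank control (0 concentration) per ring at
the last position. Concentrations default to
450/300/180/120/80/55/40/25/16/0 (arbitrary units, typically nM). The ring
radii are a design choice made here: they keep every ring separated by more
than the largest well diameter and put the 5 mm wells on a 20.5 mm ring so a
41 x 41 mm field of view contains the chip; any other non-overlapping layout
can be passed explicitly.

Classification per well (mean-ROI color, then decide):

1. **SAT** if the xyY luminance of the ROI-mean color ≥ `y_sat = 0.98`
   (near the display/sensor ceiling of 1.0; a saturated well's color is
   clipped and its ΔE is meaningless, so it is excluded from the FL test).
2. else **FL** if CIEDE2000 between the well's mean color and the same-ring
   control's mean color > `delta_e_fl = 3.0` — roughly the threshold at
   which an average observer sees two colors as clearly different.
3. else **NFL**.

ROIs are circles shrunk to `roi_shrink = 0.8` of the projected well radius,
so edge blur and slight registration error do not pull background pixels
into the mean. Color math (sRGB → Lab/xyY, D65/2°, CIEDE2000) is delegated
to scikit-image and verified in-tree against the standard 34-pair CIEDE2000
verification table to 1e-4.

Registration estimation thresholds the luminance image at
`background_median + max(0.02, 0.1 * (max - background_median))`, keeps
connected blobs of at least half the expected 5 mm well area, and fits a
circle (Kåsa least squares) through the outer-ring blob centroids. Rotation
is *not* estimated automatically — with one control well per ring the
brightness pattern is nearly 10-fold symmetric, so rotation must be given by
the operator. The fit needs ≥ 3 outer-ring blobs.

## Synthetic data generators

`simulate_transmission` produces `%T = 100 * exp(-slope * C * d)` plus
i.i.d. Gaussian noise (clipped to (1e-9, 100]) on a 350–700 nm, 5 nm grid by
default with triplicate replicates, seeded via `numpy.random.default_rng`.

`render_chip_image` composites well discs over a uniform background:
intensity = `gain * concentration * attenuation(depth)`, additively in the
emission color, then hard-clips to [0, 1] (sensor saturation), then adds
seeded Gaussian noise. Depth attenuation through an overlying film uses the
diffusion approximation `mu_eff = sqrt(3 * mu_a * (mu_a + mu_s'))` applied
at both the excitation and emission bands (`exp(-(mu_eff_ex + mu_eff_em) *
z)`), with a Beer–Lambert total-attenuation option for comparison. Wells
smaller than one pixel are rendered as a single-pixel disc so their ROI is
never empty. Depth series derive per-image seeds with
`numpy.random.SeedSequence.spawn`, so images are independent but the whole
series is reproducible from one seed.

Generator limitations, stated plainly:

- No point-spread function, vignetting, chromatic response, demosaicing, or
  Poisson (shot) noise — only additive Gaussian read-like noise.
- The diffusion approximation is poor at small depths and high absorption;
  it is used as a monotone, parameterized attenuation proxy, not a radiative
  transport solution.
- Fluorescence is rendered as a fixed emission color scaled linearly with
  concentration: no spectral emission shape, no inner-filter effects, no
  photobleaching.
- Backgrounds are uniform; real gel films have texture and autofluorescence
  gradients.

## Quantities this package cannot reproduce (limitations)

Several headline numbers from the experimental characterization that
motivated this package are *measurements on physical samples or clinical
images*, and no code path here can recompute them. They are recorded so that
nobody mistakes their absence for a defect:

- Clinically observed CIEDE2000 contrasts between fluorescing and
  non-fluorescing tissue regions of **15.3**, **7.8**, **6.7**, and **4.3**
  came from surgical fluorescence images of real patients. Reproducing them
  requires those images; the package only provides the ΔE machinery and
  synthetic scenes.
- Bench spectrophotometer measurements of cast phantom films gave
  `mu_a = 1.47 +/- 0.01 cm^-1` and `2.28 +/- 0.03 cm^-1`; these depend on
  the physical dye lots and cast thickness and can only be *targeted*, not
  recomputed, by `design_recipe`.
- The absorber mixture of 0.041 g/L hemoglobin, 0.030% yellow food
  coloring, and 0.03378 g/L Direct Red 81 reflects calibration slopes
  measured on specific commercial dye stocks. The shipped code solves the
  same mixture equations but cannot regenerate those concentrations without
  the original per-dye calibration spectra.

## Problem sizes and numerics

- Tests render chips at 50 µm/px on ~600 x 600 px images (desk-scale,
  seconds per test); spectra use ≤ 601-wavelength grids.
- All randomness flows through explicit integer seeds; derived seeds stay
  below 2^31.
- Everything is float64; no iterative solvers are used anywhere — every
  inversion in the recipe and spectroscopy modules is closed-form, and the
  two least-squares fits (exponential log-fit, Kåsa circle) are linear.

## Open design decisions

- The 3.0 ΔE threshold, 0.98 saturation luminance, and 0.8 ROI shrink are
  defaults chosen for the synthetic scenes; real devices should calibrate
  them (all are `ClassifierConfig` parameters).
- The adipose mid-bracket weight guard (≥ 50% Rayleigh–Mie) is a policy, not
  physics.
- Mean-color-then-ΔE (rather than per-pixel ΔE then mean) is the pinned ROI
  comparison convention; the test suite demonstrates the two differ.
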