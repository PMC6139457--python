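# Methods

This document specifies the measurement model, the calibration
algorithm, the default parameters, and the scope and numerical choices
of the synthetic rig. Units are centimetres, volts, milliseconds and
degrees throughout.

## 1. Coordinate frames

Two frames connect everything (`gazecal.geometry`):

* **Screen frame** — 2-D coordinates on the horizontal display plane,
  origin at the work-area center, `x` along the screen width (positive
  right), `y` in depth (positive away from the body).
* **Eye frame** — Cartesian 3-D, origin at the eyeball center, `X'`
  right, `Y'` straight ahead, `Z'` up.

The display plane is `Z' = o_z` with the screen origin at
`o = (o_x, o_y, o_z)` in the eye frame; default `o = (0, 30, −30)` cm,
i.e. the work-area center is 30 cm ahead of and 30 cm below the eyes.
The frames differ by a pure translation, so the eye-frame coordinates of
a screen point are also the gaze vector to that point.

Visual angles: azimuth `θ = atan2(X', Y')` (0 = straight ahead,
positive right), elevation `φ` measured from the horizontal `X'Y'` plane
(negative looking down; a colatitude-from-`Z'` convention is available
via `elevation_from_plane=False`). The angular distance between two
gaze vectors is computed as `atan2(|u×v|, u·v)` — equivalent to the
arccos of the normalized dot product but well conditioned near 0°, and
exactly 0 for identical vectors.

A space-time display-latency model (`display_latency`) captures the
top-to-bottom raster draw: latency grows linearly with vertical distance
from a reference spot at `frame_period / screen_extent` ms/cm by
default (0.556 ms/cm at 60 Hz over a 30 cm panel), or at a slope
measured with a two-photoresistor probe.

## 2. Forward (rig) model

`TrackerForwardModel` is a pinhole camera at `(0, 55, −35)` cm in the
eye frame, optical axis aimed at the eyeball center, watching the pupil
of an eyeball of radius 1.2 cm. When the eye fixates screen point `p`,
the pupil sits on the sphere surface along the gaze direction; its
perspective projection onto the image plane, scaled by a per-channel
focal gain and shifted by a per-channel offset, gives the two output
voltages. `TrackerForwardModel.for_rig(geometry, span_volts=3)`
mirrors the bench procedure of adjusting tracker gain and offset until
the work-area corners and center span ±3 V.

This geometry reproduces the characteristic perspective compression: on
the default 20 × 9 cm monkey work area, the near half of the depth axis
spans 3.26 V and the far half only 2.85 V, and the voltage grid of a
uniform 5 × 5 target grid is visibly pincushioned.

Voltages are quantized to an ADC step of 2⁻¹⁵ V (16-bit converter over
±1 V ranges are typical; any representable step works) and clipped to
±5 V with a saturation flag. Quantization matters beyond realism: a
head-shift offset that is representable on the ADC grid cancels
*bitwise* under drift correction (§5).

`PolynomialInverseForwardModel` is a second forward model whose exact
cm → V map is the inverse (via 2-D Newton iteration) of a known
polynomial V → cm pair; it provides ground truth for which a
polynomial calibration should be *exact*, used in tests.

### Session generator

`generate_fixation_session(targets, forward_model, noise, geometry)`
produces fixation trials: per target and repeat, a 100 ms window at
1 kHz (100 samples), repeats presented in independently shuffled order,
timestamps advancing across trials with a 400 ms intertrial gap. The
noise model applies, in order:

1. per-trial fixation scatter — a (θ, φ) offset with per-axis SD
   `trial_scatter_deg_sd`;
2. per-sample oculomotor jitter — i.i.d. (θ, φ) noise with per-axis SD
   `sample_noise_deg_rms / 2`;
3. angular → screen → forward model (unquantized);
4. additive Gaussian voltage noise (`voltage_noise_v`);
5. ADC quantization and clipping;
6. blinks: with probability `blink_prob` per trial, a contiguous window
   of 30 % of the samples is driven 1 V above the voltage ceiling and
   flagged invalid;
7. an optional constant head-shift voltage offset.

Jitter semantics: for i.i.d. per-axis jitter of SD σ the RMS of angular
distances between successive samples is `σ·√(2(1+cos²φ))`, which equals
`2σ` for straight-ahead gaze; the generator therefore uses
`σ = sample_noise_deg_rms / 2`. At the working elevation of ≈ −45° the
realized RMS is ≈ 0.87 × nominal, an accepted approximation.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; sessions are bit-reproducible.

## 3. Calibration

`calibrate_session(session, order=4)` chains four stages
(`gazecal.calibrate`):

1. **Sample selection** (`select_samples`) — drops samples flagged
   invalid, outside the voltage range, or farther than
   5 × (1.4826 · MAD) from the per-channel median (a robust-SD gate
   that removes unflagged saccades/blinks); reports per-reason counts
   and raises `UnusableTrialError` when nothing survives.
2. **Anchor averaging** (`average_anchors`) — pools retained samples
   across repeats of each target into one mean-voltage anchor per
   target (25 for the standard grid); `MissingTargetError` names any
   target left without usable trials.
3. **Biharmonic regrid** (`regrid_biharmonic`) — interpolates the
   scattered anchors onto a dense 50 × 50 voltage lattice with a
   biharmonic (thin-plate-type) spline: Green's function
   `g(r) = r²(ln r − 1)` plus an affine term, solved as a bordered
   linear system after scaling the anchor voltages to the unit box.
   This is the classic scattered-data "V4" interpolant; it passes
   exactly through the anchors and reproduces affine maps to ≤ 1e−8.
   Duplicate or collinear anchors are rejected with specific messages.
4. **Polynomial fit** (`fit_polynomial`) — least squares of the mesh
   (default, `fit_on="mesh"`) or the raw anchors (`fit_on="anchors"`)
   onto a total-degree polynomial basis in the two voltages: 6, 10, or
   15 terms for order 2, 3, 4. Voltages are affinely normalized to
   [−1, 1]² before building the Vandermonde matrix; a design-matrix
   condition number above 1e10 aborts the fit. Residuals are always
   reported at the anchors.

The regrid step regularizes the problem: 25 anchors barely determine 15
quartic coefficients, while the 2500-node mesh carries the spline's
smooth interpolation of the perspective distortion into the fit.
`fit_on="anchors"` is the right choice when the underlying map is known
to be polynomial (it is then exact to rounding); `fit_on="mesh"` is the
robust default for real rigs.

The model serializes to JSON (`c_ij` coefficient keys, normalization,
valid voltage box, provenance) and round-trips bitwise.

## 4. Reconstruction

`voltages_to_gaze` evaluates the fitted polynomial; samples outside the
fit's voltage bounding box are returned but flagged `extrapolated`, and
non-finite inputs yield NaN rows with the flag set rather than raising.
`gaze_to_angles` converts screen positions to `(ρ, θ, φ)`;
`reconstruct_session` emits a tidy per-sample DataFrame;
`fixation_errors` averages the retained samples of each trial, and
reports per-trial angular error plus signed θ/φ errors against the
target.

## 5. Drift correction

A rigid head/camera displacement adds, to first order, a constant
voltage offset on both channels. `estimate_drift(current, calibration)`
computes `dv = mean(calibration) − mean(current)` from center-target
fixations recorded at calibration time and now; `apply_drift` adds `dv`
to raw voltages before reconstruction. Only one known target is needed
— the full grid never has to be re-run.

With noise-free voltages and an ADC-representable shift the correction
is bit-exact: sums and means of grid values are exactly representable,
so `(v + dv) − dv == v` bitwise, and the reconstructed positions are
identical. Under artificial-eye-grade noise (0.0054° RMS jitter, 0.05°
scatter, 1 mV voltage noise), a (+0.25, −0.125) V shift raises the
median validation error from 0.056° to 1.22°; the offset estimated from
ten center fixations restores an error distribution that a rank-sum test
cannot distinguish from the pre-shift one (p ≈ 0.9), while the shifted
one differs at p < 1e−8.

## 6. Validation metrics

* **accuracy** — median absolute angular error across trials.
* **precision_iqr** — interquartile range of the error distribution
  (linear-interpolation quantiles).
* **precision_rms** — RMS of angular distances between successive
  fixation samples (the Holmqvist tracker-noise measure).
* **compare_distributions** — two-sided Wilcoxon rank-sum p-value.
* **f_test_variance** — two-sided variance-ratio test.
* **shift_boundaries** — for a normal voltage distribution (SD σ, n
  per group), the mean shifts a two-sample t-test would call maximally
  non-significant and minimally significant; found by root-finding on
  the expected t statistic (closed form `t_crit·σ·√(2/n)`), returned as
  boundary ∓ σ/20.
* **discriminability_table** — draws one base voltage distribution,
  *translates the same sample* by each boundary shift along each axis
  (so the t statistic is at its expected value rather than a random
  draw), reconstructs, converts to angles, and t-/F-tests each shifted
  set against the original. A well-behaved calibration keeps
  significant shifts significant on the shifted axis only, keeps
  sub-threshold shifts non-significant, and leaves all F-tests
  non-significant.

## 7. Session file format

Plain text: a `# gazecal-session v1` tag line, a `# meta: {json}`
header (geometry, units, sampling rate, provenance), then CSV with
columns `trial_id, target_x_cm, target_y_cm, t_ms, xv_volts, yv_volts,
valid`. Floats are written with 17 significant digits so voltages
round-trip bitwise. Readers validate units, rate, column presence,
per-trial timestamp monotonicity, and report malformed rows by line
number. Writes are atomic (temp file + rename).

## 8. Defaults

| parameter | default | rationale |
|---|---|---|
| screen origin `o` | (0, 30, −30) cm | display ~30 cm ahead/below the eyes |
| work area | 20 × 9 cm (monkey), 28 × 28 cm (human) | rig work spaces |
| camera position | (0, 55, −35) cm | above/behind the display edge, oblique view |
| eyeball radius | 1.2 cm | primate eye |
| tracker span | ±3 V over the work area | bench gain/offset procedure |
| ADC step | 2⁻¹⁵ V | 16-bit converter |
| trial window | 100 ms at 1 kHz | fixation hold window |
| calibration grid | 5 × 5, 3 repeats | standard grid |
| regrid lattice | 50 × 50 | dense vs. 25 anchors; fit cost trivial |
| polynomial order | 4 (15 terms/axis) | captures the perspective map |
| robust gate | median ± 5 × 1.4826·MAD | removes saccades/blinks |
| monkey noise | 0.048° RMS jitter, 0.1°/axis scatter | behaving-animal grade |
| artificial-eye noise | 0.0054° RMS jitter | bench grade |

## 9. Scope and limitations

* The forward model is a single idealized pinhole camera; it omits lens
  distortion, corneal refraction, pupil-size changes, and torsion.
  The calibration, however, never assumes the forward model — only
  smoothness of the voltage → position map.
* Drift correction assumes a *constant* voltage offset (rigid shift,
  first order). Rotational head movements or gain drift need
  recalibration.
* The noise model is Gaussian and stationary within a session; real
  oculomotor noise has heavier tails (the robust selection gate exists
  for exactly that reason).
* `fixation_errors` reduces each trial to its mean retained sample;
  per-sample error analysis is available through
  `reconstruct_session`.
* Angles assume a cyclopean eye at the eye-frame origin; binocular
  parallax over the workspace is not modeled.
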