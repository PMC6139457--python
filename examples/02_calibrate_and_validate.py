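"""Full pipeline: simulate fixations, calibrate, reconstruct, validate.

Generates a calibration session under monkey-grade fixation noise, fits
the voltage->position map (anchors -> biharmonic regrid -> quartic
polynomial), then measures accuracy and precision on 25 random targets
the calibration never saw.  Also compares polynomial orders 2/3/4.
"""

import numpy as np

from gazecal import (
    NoiseModel,
    RigGeometry,
    TrackerForwardModel,
    calibrate_session,
    compare_orders,
    fixation_errors,
    generate_calibration_grid,
    generate_fixation_session,
    metrics_report,
)

rig = RigGeometry.monkey_default()
tracker = TrackerForwardModel.for_rig(rig)
noise = NoiseModel(sample_noise_deg_rms=0.048, trial_scatter_deg_sd=0.1)

# --- calibrate on a 5 x 5 grid, 3 repeats per target -------------------
grid = generate_calibration_grid(rig.work_area_cm)
cal_session = generate_fixation_session(grid, tracker, noise, rig, seed=11)
model = calibrate_session(cal_session, order=4)
print(f"quartic fit: {len(model.coeffs_x)} terms/axis, "
      f"training RMS {model.rms_residual_cm:.4f} cm")

# --- validate on random targets ----------------------------------------
rng = np.random.default_rng(12)
targets = np.column_stack([rng.uniform(-10, 10, 25), rng.uniform(-4.5, 4.5, 25)])
val_session = generate_fixation_session(targets, tracker, noise, rig, seed=13)
errors = fixation_errors(val_session, model)
report = metrics_report(errors)
print(f"\nvalidation on 25 unseen random targets ({report.n_trials} trials):")
print(f"  accuracy (median error) : {report.accuracy_deg:.4f} deg")
print(f"  precision (error IQR)   : {report.precision_iqr_deg:.4f} deg")
print(f"  mean error              : {errors['angular_error_deg'].mean():.4f} deg")

# --- does polynomial order matter? -------------------------------------
models = [calibrate_session(cal_session, order=k) for k in (2, 3, 4)]
cmp = compare_orders(models, val_session)
print("\nmean validation error by polynomial order:")
for k in (2, 3, 4):
    print(f"  order {k}: {cmp.mean_error_deg[k]:.4f} deg")
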