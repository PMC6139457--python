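"""Does the nonlinear reconstruction preserve eye-position discriminability?

Two voltage distributions that a t-test can barely tell apart (or barely
cannot) are pushed through the quartic reconstruction and the
visual-angle conversion.  If the map were badly behaved, a significant
difference could vanish, leak onto the other axis, or change shape.  The
table shows none of that happens.
"""

import numpy as np

from gazecal import (
    NoiseModel,
    RigGeometry,
    TrackerForwardModel,
    calibrate_session,
    discriminability_table,
    generate_calibration_grid,
    generate_fixation_session,
)

rig = RigGeometry.monkey_default()
tracker = TrackerForwardModel.for_rig(rig)
grid = generate_calibration_grid(rig.work_area_cm)
cal = generate_fixation_session(grid, tracker, NoiseModel(), rig, seed=1)
model = calibrate_session(cal, order=4)

center_v, _ = tracker.voltages(np.zeros(2), rig)
table = discriminability_table(model, rig, center_v, (0.02, 0.02), n=1000, seed=1000)

with np.printoptions(precision=4):
    for block, rows in table.groupby("block", sort=False):
        print(f"\n{block}:")
        for _, r in rows.iterrows():
            print(f"  {r['shift']}  ({r['shift_v']:+.6f} V)   "
                  f"t-test theta p={r['t_test_theta_p']:.4f}  phi p={r['t_test_phi_p']:.4f}   "
                  f"F-test theta p={r['f_test_theta_p']:.4f}  phi p={r['f_test_phi_p']:.4f}")

print("\nreading: in the 'different' block only the shifted axis is significant "
      "(p < 0.05); in the 'same' block nothing is; all F-tests stay "
      "non-significant, so the distribution shapes are preserved.")
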