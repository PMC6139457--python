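"""Simulate the artificial-eye rig and show the perspective nonlinearity.

The tracker camera looks obliquely down at the eyeball, so equal steps
in screen position map to *unequal* steps in output voltage: targets far
from the body are compressed.  This is the nonlinearity the calibration
has to undo.
"""

import numpy as np

from gazecal import RigGeometry, TrackerForwardModel, generate_calibration_grid

rig = RigGeometry.monkey_default()          # 20 x 9 cm horizontal work area
tracker = TrackerForwardModel.for_rig(rig)  # gain/offset tuned to +-3 V span

grid = generate_calibration_grid(rig.work_area_cm)   # 5 x 5 targets
volts, saturated = tracker.voltages(grid, rig)

print("5 x 5 calibration grid (screen cm -> tracker volts):")
for (x, y), (vx, vy) in zip(grid, volts):
    print(f"  ({x:6.1f}, {y:4.1f}) cm  ->  ({vx:+7.4f}, {vy:+7.4f}) V")

# depth compression: the same 4.5 cm step in y spans fewer volts when it
# happens at the far edge of the work area than at the near edge
near = tracker.voltages(np.array([[0.0, -4.5], [0.0, 0.0]]), rig)[0]
far = tracker.voltages(np.array([[0.0, 0.0], [0.0, 4.5]]), rig)[0]
print(f"\nnear 4.5 cm depth step: {near[1, 1] - near[0, 1]:.4f} V")
print(f"far  4.5 cm depth step: {far[1, 1] - far[0, 1]:.4f} V")
print("-> a linear (gain/offset) calibration cannot be exact everywhere")
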