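"""Artificial-eye rig simulator: forward model, sessions, head shifts."""

import numpy as np
import pytest
from scipy import stats

from gazecal import (
    NoiseModel,
    RigGeometry,
    TrackerForwardModel,
    apply_head_shift,
    forward_voltages,
    generate_calibration_grid,
    generate_fixation_session,
)


class TestForwardModel:
    def test_determinism(self, tracker, rig, grid):
        v1, _ = tracker.voltages(grid, rig)
        v2, _ = tracker.voltages(grid, rig)
        assert np.array_equal(v1, v2)

    def test_grid_within_voltage_range(self, tracker, rig, grid):
        v, saturated = tracker.voltages(grid, rig)
        lo, hi = tracker.voltage_range
        assert np.all((v >= lo) & (v <= hi))
        assert not saturated.any()

    def test_depth_dependent_compression(self, tracker, rig):
        """Equal cm separations at different depths give unequal voltage steps."""
        near, _ = tracker.voltages(np.array([[0.0, -4.5], [2.0, -4.5]]), rig)
        far, _ = tracker.voltages(np.array([[0.0, 4.5], [2.0, 4.5]]), rig)
        d_near = near[1, 0] - near[0, 0]
        d_far = far[1, 0] - far[0, 0]
        assert abs(d_near - d_far) > 0.01  # volts; perspective, not affine

    def test_monotone_along_primary_axes(self, tracker, rig):
        xs = np.linspace(-10, 10, 41)
        for y in (-4.5, 0.0, 4.5):
            vx = tracker.voltages(np.column_stack([xs, np.full_like(xs, y)]), rig)[0][:, 0]
            assert np.all(np.diff(vx) > 0) or np.all(np.diff(vx) < 0)
        ys = np.linspace(-4.5, 4.5, 41)
        for x in (-10.0, 0.0, 10.0):
            vy = tracker.voltages(np.column_stack([np.full_like(ys, x), ys]), rig)[0][:, 1]
            assert np.all(np.diff(vy) > 0) or np.all(np.diff(vy) < 0)

    def test_linear_limit_proportional_voltages(self):
        """Camera far away along the vertical: image coords ~ proportional to cm."""
        g = RigGeometry(screen_origin_in_eye_frame=(0.0, 0.0, -30.0), work_area_cm=(4, 4))
        fm = TrackerForwardModel(
            camera_position=(0.0, 0.0, -1e6),
            focal_gain=(1e6, 1e6),
            voltage_range=(-1e9, 1e9),
            quantization_v=0.0,
        )
        # small offsets: the imaged pupil sits on the eyeball sphere, so the
        # map is proportional only in the small-angle limit
        p = np.array([[0.0, 0.0], [0.02, 0.0], [0.04, 0.0], [0.0, 0.02], [0.0, 0.04]])
        v, _ = forward_voltages(p, fm, g)
        v = v - v[0]
        # doubling the cm offset doubles the voltage to first order
        assert v[2, 0] / v[1, 0] == pytest.approx(2.0, rel=1e-4)
        assert v[4, 1] / v[3, 1] == pytest.approx(2.0, rel=1e-4)

    def test_camera_at_eye_center_rejected(self):
        with pytest.raises(ValueError):
            TrackerForwardModel(camera_position=(0.0, 0.0, 0.0))


class TestCalibrationGrid:
    def test_5x5_spans_monkey_work_area(self):
        g = generate_calibration_grid((20.0, 9.0))
        assert g.shape == (25, 2)
        corners = {(-10.0, -4.5), (10.0, -4.5), (-10.0, 4.5), (10.0, 4.5)}
        assert corners <= set(map(tuple, g))
        assert len(np.unique(g, axis=0)) == 25

    def test_2x2_grid_is_corners(self):
        g = generate_calibration_grid((20.0, 9.0), 2, 2)
        assert set(map(tuple, g)) == {(-10.0, -4.5), (10.0, -4.5), (-10.0, 4.5), (10.0, 4.5)}

    def test_row_major_order(self):
        g = generate_calibration_grid((20.0, 9.0), 3, 3)
        assert np.all(np.diff(g[:3, 0]) > 0)  # first row sweeps x
        assert g[0, 1] == g[1, 1] == g[2, 1]

    @pytest.mark.parametrize("bad", [((0, 9),), ((20, -1),)])
    def test_degenerate_area_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_calibration_grid(*bad)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_calibration_grid((20, 9), 1, 5)


class TestSessionGeneration:
    def test_noise_free_samples_equal_forward_voltages(self, clean_session, tracker, rig):
        for tr in clean_session.trials[:5]:
            expected, _ = tracker.voltages(tr.target_cm, rig)
            assert np.all(tr.volts == expected)
            assert np.all(tr.volts[0] == tr.volts)  # identical within trial

    def test_seed_determinism(self, grid, tracker, rig):
        noise = NoiseModel(sample_noise_deg_rms=0.05, trial_scatter_deg_sd=0.1, blink_prob=0.2)
        a = generate_fixation_session(grid, tracker, noise, rig, seed=9)
        b = generate_fixation_session(grid, tracker, noise, rig, seed=9)
        assert all(
            np.array_equal(x.volts, y.volts) and np.array_equal(x.valid, y.valid)
            for x, y in zip(a.trials, b.trials)
        )

    def test_presentation_order_is_randomized(self, grid, tracker, rig):
        s = generate_fixation_session(grid, tracker, NoiseModel(), rig, seed=9)
        first_repeat = np.array([t.target_cm for t in s.trials[:25]])
        assert not np.array_equal(first_repeat, grid)  # shuffled
        assert len(np.unique(first_repeat, axis=0)) == 25  # each target once

    def test_trial_counts_and_timestamps(self, clean_session):
        assert len(clean_session.trials) == 75  # 25 targets x 3 repeats
        t_all = np.concatenate([t.t_ms for t in clean_session.trials])
        assert np.all(np.diff(t_all) > 0)  # globally increasing at 1 kHz
        assert all(len(t) == 100 for t in clean_session.trials)

    def test_blink_trials_flagged_out_of_range(self, grid, tracker, rig):
        noise = NoiseModel(blink_prob=1.0)
        s = generate_fixation_session(grid[:4], tracker, noise, rig, seed=2)
        hi = tracker.voltage_range[1]
        for tr in s.trials:
            assert (~tr.valid).any()
            assert np.all(tr.volts[~tr.valid] > hi)

    def test_empty_targets_rejected(self, tracker, rig):
        with pytest.raises(ValueError):
            generate_fixation_session(np.empty((0, 2)), tracker, NoiseModel(), rig, seed=0)

    def test_jitter_parameter_matches_rms_precision(self, rig):
        """Per-axis SD = rms/2 gives the requested successive-sample RMS
        for straight-ahead gaze; at elevation phi the realized RMS is
        scaled by sqrt((1 + cos^2 phi) / 2) because azimuthal arc length
        shrinks with cos(phi).  Monte Carlo at n=1e5.
        """
        from gazecal import angles_to_screen, precision_rms, screen_to_eye_frame

        rms_target = 0.2
        rng = np.random.default_rng(0)
        sd = rms_target / 2
        for phi0 in (-1.0, -45.0):
            th = rng.normal(0, sd, 100_000)
            ph = rng.normal(0, sd, 100_000) + phi0
            vec = screen_to_eye_frame(angles_to_screen(th, ph, rig), rig)
            scale = np.sqrt((1 + np.cos(np.radians(phi0)) ** 2) / 2)
            assert precision_rms(vec) == pytest.approx(rms_target * scale, rel=0.02)


class TestHeadShift:
    def test_zero_shift_is_identity(self, clean_session):
        s = apply_head_shift(clean_session, (0.0, 0.0))
        assert all(np.array_equal(a.volts, b.volts) for a, b in zip(s.trials, clean_session.trials))

    def test_additive_inverse_restores_exactly(self, clean_session):
        dv = (0.1, -0.2)
        s = apply_head_shift(apply_head_shift(clean_session, dv), (-dv[0], -dv[1]))
        assert all(np.array_equal(a.volts, b.volts) for a, b in zip(s.trials, clean_session.trials))

    def test_commutes_with_generation(self, grid, tracker, rig):
        dv = np.array([0.25, -0.125])
        noise = NoiseModel(sample_noise_deg_rms=0.05, head_shift_v=tuple(dv))
        direct = generate_fixation_session(grid, tracker, noise, rig, seed=4)
        base = generate_fixation_session(
            grid, tracker, NoiseModel(sample_noise_deg_rms=0.05), rig, seed=4
        )
        shifted = apply_head_shift(base, dv)
        assert all(np.array_equal(a.volts, b.volts) for a, b in zip(direct.trials, shifted.trials))

    def test_shift_changes_voltage_distribution(self, grid, tracker, rig):
        noise = NoiseModel(sample_noise_deg_rms=0.05, trial_scatter_deg_sd=0.1)
        base = generate_fixation_session(grid, tracker, noise, rig, seed=5)
        shifted = apply_head_shift(base, (0.1, -0.2))
        a = np.concatenate([t.volts[:, 0] for t in base.trials])
        b = np.concatenate([t.volts[:, 0] for t in shifted.trials])
        assert stats.ranksums(a, b).pvalue < 1e-4

    def test_provenance_records_shift(self, clean_session):
        s = apply_head_shift(clean_session, (0.1, 0.2))
        assert s.provenance["head_shift_applied_v"] == [0.1, 0.2]
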