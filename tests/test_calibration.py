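"""Sample selection, anchor averaging, biharmonic regrid, polynomial fits."""

import numpy as np
import pytest

from gazecal import (
    BiharmonicSpline,
    MissingTargetError,
    NoiseModel,
    RejectionPolicy,
    TargetVoltageAnchor,
    UnusableTrialError,
    average_anchors,
    calibrate_session,
    compare_orders,
    fit_polynomial,
    generate_fixation_session,
    regrid_biharmonic,
    select_samples,
)
from gazecal.calibrate import _basis_exponents
from gazecal.simulate import BLINK_EXCURSION_V, FixationTrial


def make_trial(volts, valid=None, trial_id=0):
    n = len(volts)
    return FixationTrial(
        trial_id, np.zeros(2), np.arange(n, dtype=float), np.asarray(volts, float),
        np.ones(n, bool) if valid is None else np.asarray(valid, bool),
    )


class TestSelectSamples:
    def test_clean_trial_fully_retained(self, clean_session):
        sel = select_samples(clean_session.trials[0])
        assert sel.n_retained == sel.n_total

    def test_blink_excursion_rejected_rest_kept(self, tracker):
        hi = tracker.voltage_range[1]
        v = np.tile([1.0, -0.5], (100, 1))
        valid = np.ones(100, bool)
        v[40:70] = hi + BLINK_EXCURSION_V
        valid[40:70] = False
        sel = select_samples(make_trial(v, valid))
        assert sel.n_retained == 70
        assert sel.n_flagged_invalid == 30
        assert np.array_equal(np.nonzero(~sel.mask)[0], np.arange(40, 70))

    def test_unflagged_outlier_rejected_by_robust_sd(self):
        v = np.tile([1.0, -0.5], (100, 1))
        v += np.random.default_rng(0).normal(0, 0.001, v.shape)
        v[10] = [3.0, -0.5]  # saccade-like excursion without a validity flag
        sel = select_samples(make_trial(v))
        assert not sel.mask[10]
        assert sel.n_outlier == 1

    def test_empty_trial_unusable(self):
        with pytest.raises(UnusableTrialError):
            select_samples(make_trial(np.empty((0, 2))))

    def test_all_rejected_reported_not_dropped(self):
        v = np.tile([1.0, 1.0], (10, 1))
        with pytest.raises(UnusableTrialError, match="all 10 samples rejected"):
            select_samples(make_trial(v, valid=np.zeros(10, bool)))


class TestAverageAnchors:
    def test_noise_free_anchor_equals_forward_voltages(self, clean_session, tracker, rig):
        anchors = average_anchors(clean_session)
        assert len(anchors) == 25
        for a in anchors:
            expected, _ = tracker.voltages(a.target_cm, rig)
            assert np.allclose(a.mean_voltage, expected, atol=1e-12)
            assert a.n_samples == 300  # 3 repeats x 100 samples

    def test_blink_contaminated_repeat_still_close(self, grid, tracker, rig):
        noise = NoiseModel(voltage_noise_v=0.003, blink_prob=0.33)
        s = generate_fixation_session(grid, tracker, noise, rig, seed=12)
        anchors = average_anchors(s)
        sem = 0.003 / np.sqrt(200)  # conservative: >=200 retained samples
        for a in anchors:
            clean, _ = tracker.voltages(a.target_cm, rig)
            assert np.all(np.abs(a.mean_voltage - clean) < 3 * sem + 3e-4)

    def test_missing_target_reported_by_name(self, clean_session):
        partial = type(clean_session)(
            [t for t in clean_session.trials if not np.allclose(t.target_cm, [10.0, 4.5])],
            clean_session.geometry,
        )
        # drop the far-corner target entirely: 24 targets remain covered
        partial.trials.append(
            FixationTrial(999, np.array([10.0, 4.5]), np.array([0.0]),
                          np.array([[0.0, 0.0]]), np.array([False]))
        )
        with pytest.raises(MissingTargetError) as e:
            average_anchors(partial)
        assert (10.0, 4.5) in e.value.targets


def affine_anchors(n_side=5, a=0.3, b=-0.1, c=2.0):
    rng = np.random.default_rng(0)
    volts = rng.uniform(-2, 2, size=(n_side * n_side, 2))
    x = c + a * volts[:, 0] + b * volts[:, 1]
    y = -1.0 + 0.5 * volts[:, 0] + 1.5 * volts[:, 1]
    return [
        TargetVoltageAnchor(np.array([xi, yi]), v, 10, np.zeros(2))
        for v, xi, yi in zip(volts, x, y)
    ]


class TestBiharmonicRegrid:
    def test_reproduces_affine_maps_exactly(self):
        anchors = affine_anchors()
        mesh = regrid_biharmonic(anchors, resolution=20)
        nodes = mesh.nodes
        expected_x = 2.0 + 0.3 * nodes[:, 0] - 0.1 * nodes[:, 1]
        expected_y = -1.0 + 0.5 * nodes[:, 0] + 1.5 * nodes[:, 1]
        assert np.max(np.abs(mesh.values_x_cm.ravel() - expected_x)) < 1e-8
        assert np.max(np.abs(mesh.values_y_cm.ravel() - expected_y)) < 1e-8

    def test_interpolates_through_anchors(self, clean_session):
        anchors = average_anchors(clean_session)
        volts = np.array([a.mean_voltage for a in anchors])
        spline = BiharmonicSpline(volts, np.array([a.target_cm[0] for a in anchors]))
        assert np.max(np.abs(spline(volts) - [a.target_cm[0] for a in anchors])) < 1e-8

    def test_duplicate_anchor_reported(self):
        anchors = affine_anchors()
        anchors[3] = TargetVoltageAnchor(
            anchors[3].target_cm, anchors[2].mean_voltage, 10, np.zeros(2)
        )
        with pytest.raises(ValueError, match="duplicate"):
            regrid_biharmonic(anchors)

    def test_collinear_anchors_rejected(self):
        volts = np.column_stack([np.linspace(0, 1, 8), np.linspace(0, 2, 8)])
        with pytest.raises(ValueError, match="collinear"):
            BiharmonicSpline(volts, np.arange(8.0))

    def test_too_few_anchors_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            BiharmonicSpline(np.random.default_rng(0).uniform(size=(5, 2)), np.zeros(5))

    def test_close_to_scipy_thin_plate_on_smooth_data(self, clean_session):
        """Sanity cross-check against an independent scattered interpolant.

        scipy's thin-plate RBF uses a slightly different kernel, so the
        two interpolants agree only approximately away from the anchors.
        """
        from scipy.interpolate import RBFInterpolator

        anchors = average_anchors(clean_session)
        volts = np.array([a.mean_voltage for a in anchors])
        vals = np.array([a.target_cm[1] for a in anchors])
        ours = BiharmonicSpline(volts, vals)
        theirs = RBFInterpolator(volts, vals, kernel="thin_plate_spline")
        rng = np.random.default_rng(1)
        lo, hi = volts.min(axis=0), volts.max(axis=0)
        q = lo + (hi - lo) * rng.uniform(0.2, 0.8, size=(50, 2))
        assert np.max(np.abs(ours(q) - theirs(q))) < 0.05  # cm


class TestPolynomialFit:
    def test_basis_sizes(self):
        assert [len(_basis_exponents(k)) for k in (2, 3, 4)] == [6, 10, 15]

    def test_exact_quartic_recovery(self):
        rng = np.random.default_rng(2)
        volts = rng.uniform(-2, 2, size=(40, 2))
        exps = _basis_exponents(4)
        cx = rng.normal(0, 0.1, 15)
        cy = rng.normal(0, 0.1, 15)
        u = volts  # evaluate the target quartic directly in raw volts
        X = np.column_stack([u[:, 0] ** i * u[:, 1] ** j for i, j in exps])
        anchors = [
            TargetVoltageAnchor(np.array([xv, yv]), v, 10, np.zeros(2))
            for v, xv, yv in zip(volts, X @ cx, X @ cy)
        ]
        m = fit_polynomial(anchors, order=4)
        assert np.max(np.abs(m.fit_residuals_cm)) < 1e-9

    def test_affine_data_higher_orders_vanish(self):
        anchors = affine_anchors()
        m = fit_polynomial(anchors, order=2)
        nonlinear = [c for (i, j), c in zip(m.exponents, m.coeffs_x) if i + j > 1]
        assert np.max(np.abs(nonlinear)) < 1e-9

    def test_training_rms_non_increasing_with_order(self, grid, tracker, rig):
        noise = NoiseModel(sample_noise_deg_rms=0.048, trial_scatter_deg_sd=0.1)
        s = generate_fixation_session(grid, tracker, noise, rig, seed=13)
        anchors = average_anchors(s)
        mesh = regrid_biharmonic(anchors)
        rms = [fit_polynomial(mesh, k).rms_residual_cm for k in (2, 3, 4)]
        assert rms[0] >= rms[1] >= rms[2]

    def test_permutation_invariance(self):
        anchors = affine_anchors()
        m1 = fit_polynomial(anchors, order=3)
        m2 = fit_polynomial(list(reversed(anchors)), order=3)
        assert np.allclose(m1.coeffs_x, m2.coeffs_x, atol=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 15"):
            fit_polynomial(affine_anchors()[:10], order=4)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            fit_polynomial(affine_anchors(), order=5)

    def test_json_round_trip(self, quartic_model, tmp_path):
        from gazecal import CalibrationModel

        path = tmp_path / "model.json"
        quartic_model.to_json(path)
        back = CalibrationModel.from_json(path)
        assert np.array_equal(back.coeffs_x, quartic_model.coeffs_x)
        rng = np.random.default_rng(3)
        v = rng.uniform(-2, 2, size=(20, 2))
        assert np.array_equal(back.predict(v)[0], quartic_model.predict(v)[0])

    def test_coefficient_key_format(self, quartic_model):
        d = quartic_model.to_dict()
        assert "c_00" in d["coeffs_x"] and "c_22" in d["coeffs_x"]
        assert len(d["coeffs_x"]) == 15 and d["basis"] == "total_degree"


class TestCompareOrders:
    def test_identical_models_p_one(self, clean_session, quartic_model):
        cmp = compare_orders([quartic_model, quartic_model], clean_session)
        assert all(p == 1.0 for p in cmp.paired_t_p.values())

    def test_corrupted_model_strictly_worse(self, clean_session, quartic_model):
        import copy

        bad = copy.deepcopy(quartic_model)
        bad.coeffs_x = bad.coeffs_x.copy()
        bad.coeffs_x[3] += 0.5
        bad.order = 3  # distinct key for the comparison table
        bad.exponents = bad.exponents[:10]
        bad.coeffs_x = bad.coeffs_x[:10]
        bad.coeffs_y = bad.coeffs_y[:10]
        cmp = compare_orders([quartic_model, bad], clean_session)
        assert cmp.mean_error_deg[3] > cmp.mean_error_deg[4]

    def test_mean_error_non_increasing_with_order(self, clean_session, grid, tracker, rig):
        models = [calibrate_session(clean_session, order=k) for k in (2, 3, 4)]
        val = generate_fixation_session(grid, tracker, NoiseModel(), rig, seed=14)
        cmp = compare_orders(models, val)
        e = [cmp.mean_error_deg[k] for k in (2, 3, 4)]
        # orders 3 and 4 both fit the smooth perspective map to ~0.01 deg, so
        # their validation errors may tie; the quadratic is distinctly worse
        assert e[0] >= e[1] and e[0] >= e[2]
        assert max(e[1], e[2]) < 0.05
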