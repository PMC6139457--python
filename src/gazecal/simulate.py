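"""Synthetic rig: a servo-style artificial eye viewed by a pinhole tracker camera.

The forward model maps a fixated screen point to the pair of raw tracker
voltages ``(X_v, Y_v)``.  The eyeball is a sphere centered at the eye-frame
origin; the pupil center sits on its surface along the gaze direction and
is imaged by a pinhole camera placed behind the display.  Because the
display is horizontal and viewed from above, equal on-screen distances at
different depths subtend unequal rotation angles, which is exactly the
perspective nonlinearity the calibration has to undo.

Voltages are quantized to an ADC grid (the analog tracker outputs are
sampled through an A/D card) and clipped to the tracker's output range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import (
    RigGeometry,
    angles_to_screen,
    screen_to_angles,
    screen_to_eye_frame,
)

__all__ = [
    "TrackerForwardModel",
    "PolynomialInverseForwardModel",
    "NoiseModel",
    "FixationTrial",
    "FixationSession",
    "forward_voltages",
    "generate_calibration_grid",
    "generate_fixation_session",
    "apply_head_shift",
]

#: Sentinel excursion (in volts above the saturation limit) used to mark
#: blink samples, paired with valid=False flags.
BLINK_EXCURSION_V = 1.0


def quantize_voltages(volts: np.ndarray, step_v: float) -> np.ndarray:
    """Round voltages to the ADC grid (step 0 disables quantization)."""
    if step_v == 0:
        return np.asarray(volts, dtype=float)
    return np.round(np.asarray(volts, dtype=float) / step_v) * step_v


@dataclass(frozen=True)
class TrackerForwardModel:
    """Pinhole-camera forward model: screen point (cm) -> raw voltages.

    Parameters
    ----------
    camera_position : (3,) cm, eye frame
        Pinhole location (behind the display, looking back at the eye).
    camera_optical_axis : (3,)
        Viewing direction of the camera; normalized on construction.
    eyeball_radius : cm
        Pupil center is placed on the eyeball surface along the gaze
        direction.
    focal_gain : (2,) volts per image unit
        Per-channel scaling of the pinhole image coordinates.
    voltage_offset : (2,) volts
    voltage_range : (lo, hi) volts
        Saturation limits of the analog outputs.
    quantization_v : volts
        ADC resolution; outputs are rounded to multiples of this step.
        Default ``2**-15`` V (~0.03 mV, 16-bit-card scale); 0 disables.
    """

    camera_position: tuple[float, float, float] = (0.0, 55.0, -35.0)
    camera_optical_axis: tuple[float, float, float] | None = None
    eyeball_radius: float = 1.2
    focal_gain: tuple[float, float] = (400.0, 400.0)
    voltage_offset: tuple[float, float] = (0.0, 0.0)
    voltage_range: tuple[float, float] = (-5.0, 5.0)
    quantization_v: float = 2.0 ** -15

    def __post_init__(self) -> None:
        c = np.asarray(self.camera_position, dtype=float)
        if np.allclose(c, 0.0):
            raise ValueError("camera must not coincide with the eyeball center")
        if self.camera_optical_axis is None:
            axis = -c  # default: look at the eyeball center
        else:
            axis = np.asarray(self.camera_optical_axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("camera optical axis must be nonzero")
        object.__setattr__(self, "camera_optical_axis", tuple(axis / n))
        g = np.asarray(self.focal_gain, dtype=float)
        if np.any(g == 0):
            raise ValueError("focal gains must be nonzero")
        lo, hi = self.voltage_range
        if not lo < hi:
            raise ValueError("voltage_range must satisfy lo < hi")
        if self.eyeball_radius <= 0:
            raise ValueError("eyeball radius must be positive")
        if self.quantization_v < 0:
            raise ValueError("quantization step must be >= 0")

    def _camera_basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = np.asarray(self.camera_optical_axis, dtype=float)
        up = np.array([0.0, 0.0, 1.0])
        right = np.cross(up, a)
        nr = np.linalg.norm(right)
        if nr < 1e-12:
            # camera looking straight up/down: use Y' as the up reference
            right = np.cross(np.array([0.0, 1.0, 0.0]), a)
            nr = np.linalg.norm(right)
        right = right / nr
        cam_up = np.cross(a, right)
        return right, cam_up, a

    def image_coords(self, points_cm, geometry: RigGeometry) -> np.ndarray:
        """Raw pinhole image coordinates (before gain/offset) of the pupil."""
        gaze_vec = screen_to_eye_frame(points_cm, geometry)
        norms = np.linalg.norm(gaze_vec, axis=-1, keepdims=True)
        pupil = self.eyeball_radius * gaze_vec / norms
        rel = pupil - np.asarray(self.camera_position, dtype=float)
        right, cam_up, axis = self._camera_basis()
        depth = rel @ axis
        if np.any(depth <= 1e-9):
            raise ValueError("gaze direction degenerate for the camera (zero/negative depth)")
        u = (rel @ right) / depth
        v = (rel @ cam_up) / depth
        return np.stack([u, v], axis=-1)

    def voltages(self, points_cm, geometry: RigGeometry, *, quantize: bool = True):
        """Deterministic voltages for fixated screen points.

        Returns ``(volts, saturated)`` where ``saturated`` flags samples
        clipped at the output range.
        """
        uv = self.image_coords(points_cm, geometry)
        v = uv * np.asarray(self.focal_gain, dtype=float) + np.asarray(
            self.voltage_offset, dtype=float
        )
        if quantize:
            v = quantize_voltages(v, self.quantization_v)
        lo, hi = self.voltage_range
        saturated = (v < lo) | (v > hi)
        v = np.clip(v, lo, hi)
        return v, saturated

    @classmethod
    def for_rig(
        cls,
        geometry: RigGeometry,
        *,
        span_volts: float = 3.0,
        **kwargs,
    ) -> "TrackerForwardModel":
        """Adjust gain and offset so the work area fills ``±span_volts``.

        Mirrors the experimental setup step of tuning the tracker's
        analog gain/offset so the signal spans the output range over the
        work area without saturating.
        """
        base = cls(focal_gain=(1.0, 1.0), voltage_offset=(0.0, 0.0), **kwargs)
        w, d = geometry.work_area_cm
        corners = np.array(
            [[-w / 2, -d / 2], [w / 2, -d / 2], [-w / 2, d / 2], [w / 2, d / 2]]
        )
        uv_corners = base.image_coords(corners, geometry)
        uv_center = base.image_coords(np.zeros(2), geometry)
        half_span = np.max(np.abs(uv_corners - uv_center), axis=0)
        gain = span_volts / half_span
        offset = -gain * uv_center
        return replace(base, focal_gain=tuple(gain), voltage_offset=tuple(offset))


@dataclass(frozen=True)
class PolynomialInverseForwardModel:
    """Forward model whose exact volts->cm inverse is a known polynomial pair.

    Given bivariate polynomial coefficient grids ``inv_x``/``inv_y`` (the
    exact inverse maps ``x_cm = P(X_v, Y_v)``, ``y_cm = Q(X_v, Y_v)``),
    the forward voltages are found by 2-D Newton iteration.  Used to
    exercise exact round-trip contracts: a polynomial fit of the same
    order must recover the inverse to machine precision.
    """

    inv_coeffs_x: tuple  # numpy.polynomial.polynomial.polyval2d coefficient grid
    inv_coeffs_y: tuple
    voltage_range: tuple[float, float] = (-5.0, 5.0)
    quantization_v: float = 0.0

    def _inverse(self, volts: np.ndarray) -> np.ndarray:
        from numpy.polynomial.polynomial import polyval2d

        cx = np.asarray(self.inv_coeffs_x, dtype=float)
        cy = np.asarray(self.inv_coeffs_y, dtype=float)
        x = polyval2d(volts[..., 0], volts[..., 1], cx)
        y = polyval2d(volts[..., 0], volts[..., 1], cy)
        return np.stack([x, y], axis=-1)

    def _jacobian(self, volts: np.ndarray) -> np.ndarray:
        from numpy.polynomial.polynomial import polyder, polyval2d

        cx = np.asarray(self.inv_coeffs_x, dtype=float)
        cy = np.asarray(self.inv_coeffs_y, dtype=float)
        J = np.empty(volts.shape[:-1] + (2, 2), dtype=float)
        for i, c in enumerate((cx, cy)):
            J[..., i, 0] = polyval2d(volts[..., 0], volts[..., 1], polyder(c, axis=0))
            J[..., i, 1] = polyval2d(volts[..., 0], volts[..., 1], polyder(c, axis=1))
        return J

    def voltages(self, points_cm, geometry: RigGeometry, *, quantize: bool = True):
        p = np.atleast_2d(np.asarray(points_cm, dtype=float))
        v = np.zeros_like(p)
        for _ in range(60):
            r = self._inverse(v) - p
            if np.max(np.abs(r)) < 1e-13:
                break
            J = self._jacobian(v)
            step = np.linalg.solve(J, r[..., None])[..., 0]
            v = v - step
        if quantize:
            v = quantize_voltages(v, self.quantization_v)
        lo, hi = self.voltage_range
        saturated = (v < lo) | (v > hi)
        v = np.clip(v, lo, hi)
        if np.asarray(points_cm, dtype=float).ndim == 1:
            return v[0], saturated[0]
        return v, saturated


def forward_voltages(points_cm, forward_model, geometry: RigGeometry):
    """Functional wrapper: ``(volts, saturated)`` for fixated screen points."""
    return forward_model.voltages(points_cm, geometry)


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic components of a simulated fixation session.

    ``sample_noise_deg_rms`` is stated as the sample-to-sample RMS
    precision the jitter produces (per-axis Gaussian SD = rms / 2, since
    successive differences of iid isotropic jitter have RMS angular
    distance 2*sigma).  ``trial_scatter_deg_sd`` is the SD per angular
    axis of the per-trial fixation offset.  ``head_shift_v`` is a
    constant voltage offset mimicking a head displacement.
    """

    sample_noise_deg_rms: float = 0.0
    voltage_noise_v: float = 0.0
    trial_scatter_deg_sd: float = 0.0
    head_shift_v: tuple[float, float] = (0.0, 0.0)
    blink_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("sample_noise_deg_rms", "voltage_noise_v", "trial_scatter_deg_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.blink_prob <= 1.0:
            raise ValueError("blink_prob must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "sample_noise_deg_rms": self.sample_noise_deg_rms,
            "voltage_noise_v": self.voltage_noise_v,
            "trial_scatter_deg_sd": self.trial_scatter_deg_sd,
            "head_shift_v": list(self.head_shift_v),
            "blink_prob": self.blink_prob,
            "seed": self.seed,
        }


@dataclass
class FixationTrial:
    """Samples recorded while fixating one known target."""

    trial_id: int
    target_cm: np.ndarray  # (2,)
    t_ms: np.ndarray  # (n,)
    volts: np.ndarray  # (n, 2)
    valid: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.target_cm = np.asarray(self.target_cm, dtype=float)
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.volts = np.asarray(self.volts, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.t_ms) != len(self.volts) or len(self.t_ms) != len(self.valid):
            raise ValueError("trial arrays must have equal length")
        if len(self.t_ms) > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise ValueError(f"trial {self.trial_id}: timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass
class FixationSession:
    """A set of fixation trials plus the geometry and provenance that produced them."""

    trials: list[FixationTrial]
    geometry: RigGeometry
    rate_hz: float = 1000.0
    provenance: dict = field(default_factory=dict)

    def targets(self) -> np.ndarray:
        """Unique targets in first-appearance order, shape (k, 2)."""
        seen: dict[tuple[float, float], None] = {}
        for tr in self.trials:
            seen.setdefault((float(tr.target_cm[0]), float(tr.target_cm[1])), None)
        return np.array(list(seen.keys()), dtype=float)


def generate_calibration_grid(
    work_area_cm: Sequence[float], n_rows: int = 5, n_cols: int = 5
) -> np.ndarray:
    """Evenly spaced fixation-target grid spanning the work area.

    Row-major order (rows sweep depth from near to far edge, columns
    sweep left to right); the default 5 x 5 layout spans the full area,
    so corner targets sit at ``(±width/2, ±depth/2)``.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid needs at least 2 rows and 2 columns")
    w, d = float(work_area_cm[0]), float(work_area_cm[1])
    if w <= 0 or d <= 0:
        raise ValueError(f"degenerate work area {work_area_cm}")
    xs = np.linspace(-w / 2, w / 2, n_cols)
    ys = np.linspace(-d / 2, d / 2, n_rows)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def generate_fixation_session(
    targets,
    forward_model,
    noise: NoiseModel,
    geometry: RigGeometry,
    *,
    n_repeats: int = 3,
    window_ms: float = 100.0,
    rate_hz: float = 1000.0,
    seed: int | None = None,
    intertrial_gap_ms: float = 400.0,
) -> FixationSession:
    """Simulate an artificial-eye fixation session.

    For every target x repeat, the true gaze is the target plus a
    per-trial angular scatter; each 1 kHz sample adds an independent
    angular jitter; voltages come from the forward model plus additive
    sensor noise, ADC quantization, and the constant head-shift offset.
    Targets are presented in a seeded random order within each repeat.
    Blink trials (probability ``noise.blink_prob``) contain a contiguous
    out-of-range voltage excursion flagged invalid.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.size == 0:
        raise ValueError("empty target list")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if seed is None:
        seed = noise.seed if noise.seed is not None else 0
    rng = np.random.default_rng(seed)

    n_samples = int(round(window_ms * rate_hz / 1000.0))
    dt = 1000.0 / rate_hz
    qstep = getattr(forward_model, "quantization_v", 0.0)
    head_shift = np.asarray(noise.head_shift_v, dtype=float)
    lo, hi = forward_model.voltage_range

    trials: list[FixationTrial] = []
    trial_id = 0
    t0 = 0.0
    jitter_sd = noise.sample_noise_deg_rms / 2.0
    for _ in range(n_repeats):
        order = rng.permutation(len(targets))
        for idx in order:
            target = targets[idx]
            if noise.trial_scatter_deg_sd == 0 and jitter_sd == 0:
                # noise-free path: fixate the target exactly (no angle round trip)
                points = np.tile(target, (n_samples, 1))
            else:
                _, th_t, ph_t = screen_to_angles(target, geometry)
                th = th_t + rng.normal(0.0, noise.trial_scatter_deg_sd)
                ph = ph_t + rng.normal(0.0, noise.trial_scatter_deg_sd)
                if jitter_sd > 0:
                    th_s = th + rng.normal(0.0, jitter_sd, n_samples)
                    ph_s = ph + rng.normal(0.0, jitter_sd, n_samples)
                else:
                    th_s = np.full(n_samples, th)
                    ph_s = np.full(n_samples, ph)
                points = angles_to_screen(th_s, ph_s, geometry)
            volts, _ = forward_model.voltages(points, geometry, quantize=False)
            if noise.voltage_noise_v > 0:
                volts = volts + rng.normal(0.0, noise.voltage_noise_v, volts.shape)
            volts = quantize_voltages(volts, qstep)
            volts = np.clip(volts, lo, hi)
            valid = np.ones(n_samples, dtype=bool)
            if noise.blink_prob > 0 and rng.random() < noise.blink_prob:
                blen = max(1, int(round(0.3 * n_samples)))
                start = int(rng.integers(0, n_samples - blen + 1))
                volts[start : start + blen] = hi + BLINK_EXCURSION_V
                valid[start : start + blen] = False
            volts = volts + head_shift
            t_ms = t0 + dt * np.arange(n_samples)
            trials.append(FixationTrial(trial_id, target, t_ms, volts, valid))
            trial_id += 1
            t0 = t_ms[-1] + intertrial_gap_ms
    provenance = {
        "generator": "gazecal.simulate.generate_fixation_session",
        "seed": int(seed),
        "n_repeats": n_repeats,
        "window_ms": window_ms,
        "rate_hz": rate_hz,
        "noise": noise.to_dict(),
    }
    return FixationSession(trials, geometry, rate_hz=rate_hz, provenance=provenance)


def apply_head_shift(session: FixationSession, dv) -> FixationSession:
    """Return a copy of the session with a constant voltage offset added.

    Emulates a head displacement after calibration: every raw sample is
    shifted by ``dv`` volts; validity flags and timestamps are untouched.
    """
    dv = np.asarray(dv, dtype=float)
    trials = [
        FixationTrial(t.trial_id, t.target_cm.copy(), t.t_ms.copy(), t.volts + dv, t.valid.copy())
        for t in session.trials
    ]
    prov = dict(session.provenance)
    prov["head_shift_applied_v"] = prov.get("head_shift_applied_v", [0.0, 0.0])
    prov["head_shift_applied_v"] = [
        prov["head_shift_applied_v"][0] + float(dv[0]),
        prov["head_shift_applied_v"][1] + float(dv[1]),
    ]
    return FixationSession(trials, session.geometry, rate_hz=session.rate_hz, provenance=prov)
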