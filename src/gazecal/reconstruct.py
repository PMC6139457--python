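"""Apply a calibration model to raw voltage streams.

Covers drift correction (a constant compensatory voltage offset
estimated from a center-target fixation), polynomial gaze
reconstruction in screen cm, and conversion to polar visual angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import CalibrationModel, RejectionPolicy, select_samples
from .geometry import RigGeometry, angular_distance, screen_to_eye_frame, vector_to_polar
from .simulate import FixationSession, FixationTrial

__all__ = [
    "DriftOffset",
    "estimate_drift",
    "apply_drift",
    "apply_drift_session",
    "voltages_to_gaze",
    "gaze_to_angles",
    "reconstruct_session",
    "fixation_errors",
]


@dataclass(frozen=True)
class DriftOffset:
    """Compensatory voltage shift restoring calibration-epoch coordinates.

    ``dv = mean(calibration-center voltages) - mean(current-center voltages)``;
    the correction is ``corrected = raw + dv``.
    """

    dv: tuple[float, float]
    center_target_cm: tuple[float, float] = (0.0, 0.0)
    n_samples: int = 1
    estimated_at_ms: float | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.dv)):
            raise ValueError("drift offset must be finite")
        if self.n_samples <= 0:
            raise ValueError("drift offset requires n_samples > 0")

    def to_dict(self) -> dict:
        return {
            "dv_volts": list(self.dv),
            "center_target_cm": list(self.center_target_cm),
            "n_samples": self.n_samples,
            "estimated_at_ms": self.estimated_at_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DriftOffset":
        return cls(
            dv=tuple(d["dv_volts"]),
            center_target_cm=tuple(d.get("center_target_cm", (0.0, 0.0))),
            n_samples=int(d.get("n_samples", 1)),
            estimated_at_ms=d.get("estimated_at_ms"),
        )


def estimate_drift(
    current_center_volts,
    calibration_center_volts,
    *,
    center_target_cm=(0.0, 0.0),
    estimated_at_ms: float | None = None,
) -> DriftOffset:
    """Estimate the drift offset from two center-target fixations.

    Both voltage sets must come from fixations of the target at the
    center of the calibration grid: the first recorded now, the second
    during the calibration epoch.
    """
    cur = np.atleast_2d(np.asarray(current_center_volts, dtype=float))
    cal = np.atleast_2d(np.asarray(calibration_center_volts, dtype=float))
    if cur.size == 0 or cal.size == 0:
        raise ValueError("drift estimation requires non-empty center-fixation samples")
    dv = cal.mean(axis=0) - cur.mean(axis=0)
    return DriftOffset(
        dv=(float(dv[0]), float(dv[1])),
        center_target_cm=tuple(np.asarray(center_target_cm, dtype=float)),
        n_samples=len(cur),
        estimated_at_ms=estimated_at_ms,
    )


def apply_drift(volts, offset: DriftOffset) -> np.ndarray:
    """Shift raw voltages by the compensatory offset (timestamps untouched)."""
    return np.asarray(volts, dtype=float) + np.asarray(offset.dv, dtype=float)


def apply_drift_session(session: FixationSession, offset: DriftOffset) -> FixationSession:
    """Drift-correct every trial of a session."""
    trials = [
        FixationTrial(t.trial_id, t.target_cm.copy(), t.t_ms.copy(), apply_drift(t.volts, offset), t.valid.copy())
        for t in session.trials
    ]
    prov = dict(session.provenance)
    prov["drift_correction_v"] = list(offset.dv)
    return FixationSession(trials, session.geometry, rate_hz=session.rate_hz, provenance=prov)


def voltages_to_gaze(volts, model: CalibrationModel):
    """Reconstruct screen-frame gaze positions from raw voltages.

    Thin alias of :meth:`CalibrationModel.predict`: returns
    ``(points_cm, extrapolated)``; non-finite samples come back as NaN
    rows flagged extrapolated (streaming contract: no exceptions on bad
    samples).
    """
    return model.predict(volts)


def gaze_to_angles(points_cm, geometry: RigGeometry, *, elevation_from_plane: bool = True):
    """Screen-frame gaze positions to polar visual angles (rho, theta, phi)."""
    return vector_to_polar(
        screen_to_eye_frame(points_cm, geometry), elevation_from_plane=elevation_from_plane
    )


def reconstruct_session(
    session: FixationSession,
    model: CalibrationModel,
    *,
    offset: DriftOffset | None = None,
) -> pd.DataFrame:
    """Batch reconstruction of every sample in a session.

    Returns a tidy frame with one row per sample: trial id, timestamp,
    gaze in cm and visual angles, plus validity/extrapolation flags.
    """
    frames = []
    for tr in session.trials:
        v = apply_drift(tr.volts, offset) if offset is not None else tr.volts
        pts, extrap = model.predict(v)
        ok = np.all(np.isfinite(pts), axis=1)
        theta = np.full(len(pts), np.nan)
        phi = np.full(len(pts), np.nan)
        if ok.any():
            _, theta[ok], phi[ok] = gaze_to_angles(pts[ok], session.geometry)
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": tr.trial_id,
                    "t_ms": tr.t_ms,
                    "x_cm": pts[:, 0],
                    "y_cm": pts[:, 1],
                    "theta_deg": theta,
                    "phi_deg": phi,
                    "valid": tr.valid,
                    "extrapolated": extrap,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def fixation_errors(
    session: FixationSession,
    model: CalibrationModel,
    *,
    offset: DriftOffset | None = None,
    policy: RejectionPolicy | None = None,
) -> pd.DataFrame:
    """Per-trial angular error table for a validation session.

    Per trial, the fixation voltage is the mean over retained samples of
    the analysis window; the reconstructed gaze is compared with the
    trial's target as a visual angle, together with signed theta/phi
    errors (trials aligned by subtracting the target position).
    """
    rows = []
    for tr in session.trials:
        sel = select_samples(tr, policy)
        v = tr.volts[sel.mask].mean(axis=0)
        if offset is not None:
            v = apply_drift(v, offset)
        pt, extrap = model.predict(v)
        gaze_vec = screen_to_eye_frame(pt, session.geometry)
        target_vec = screen_to_eye_frame(tr.target_cm, session.geometry)
        err = angular_distance(gaze_vec, target_vec)
        _, th_g, ph_g = vector_to_polar(gaze_vec)
        _, th_t, ph_t = vector_to_polar(target_vec)
        rows.append(
            {
                "trial_id": tr.trial_id,
                "target_x_cm": tr.target_cm[0],
                "target_y_cm": tr.target_cm[1],
                "gaze_x_cm": pt[0],
                "gaze_y_cm": pt[1],
                "angular_error_deg": err,
                "dtheta_deg": th_g - th_t,
                "dphi_deg": ph_g - ph_t,
                "extrapolated": extrap,
            }
        )
    return pd.DataFrame(rows)
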