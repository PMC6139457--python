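"""Coordinate frames and angular mathematics for a horizontal-workspace gaze rig.

Two reference frames are used throughout:

* the **screen frame**: 2-D coordinates (in cm) on the horizontal display
  plane, origin at the work-area center, ``x`` along the screen width
  (positive right), ``y`` in depth (positive away from the body);
* the **eye frame**: a Cartesian 3-D frame centered on the eyeball,
  ``X'`` right, ``Y'`` ahead, ``Z'`` up.  The display plane lies below
  the eye, so the screen origin has a negative ``Z'`` coordinate.

Gaze directions live in the eye frame; visual angles are always reported
in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RigGeometry",
    "GazeAngles",
    "screen_to_eye_frame",
    "eye_frame_to_screen",
    "angular_distance",
    "vector_to_polar",
    "polar_to_vector",
    "angles_to_screen",
    "screen_to_angles",
    "display_latency",
]


@dataclass(frozen=True)
class RigGeometry:
    """Spatial layout linking the screen frame and the eye frame.

    Parameters
    ----------
    screen_origin_in_eye_frame : (3,) array-like, cm
        Coordinates ``o = (o_x, o_y, o_z)`` of the screen-frame origin
        (work-area center) expressed in the eye frame.  ``o_z`` must be
        negative: the horizontal display is viewed from above.
    work_area_cm : (width, depth), cm
        Extent of the calibrated work area.
    screen_refresh_hz : float
        Display refresh rate (Hz).
    screen_extent_cm : float
        Vertical drawing extent of the physical display panel, used by
        the space-time display-latency model.
    reference_spot_positions : two (x, y) screen points, cm
        Locations of the luminance reference spots used for display
        timing (top-left / bottom-right corners by default).
    """

    screen_origin_in_eye_frame: tuple[float, float, float] = (0.0, 30.0, -30.0)
    work_area_cm: tuple[float, float] = (20.0, 9.0)
    screen_refresh_hz: float = 60.0
    screen_extent_cm: float = 30.0
    reference_spot_positions: tuple[tuple[float, float], tuple[float, float]] = field(
        default=((-10.0, 4.5), (10.0, -4.5))
    )

    def __post_init__(self) -> None:
        o = np.asarray(self.screen_origin_in_eye_frame, dtype=float)
        if o.shape != (3,) or not np.all(np.isfinite(o)):
            raise ValueError("screen_origin_in_eye_frame must be a finite 3-vector")
        if o[2] >= 0:
            raise ValueError(
                "screen origin must lie below the eye (o_z < 0); got "
                f"o_z={o[2]!r}"
            )
        w, d = self.work_area_cm
        if not (w > 0 and d > 0):
            raise ValueError(f"work area must have positive width and depth, got {self.work_area_cm}")
        if not self.screen_refresh_hz > 0:
            raise ValueError("screen_refresh_hz must be positive")
        if not self.screen_extent_cm > 0:
            raise ValueError("screen_extent_cm must be positive")

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.screen_origin_in_eye_frame, dtype=float)

    @classmethod
    def monkey_default(cls) -> "RigGeometry":
        """20 x 9 cm work area (primate rig)."""
        return cls(work_area_cm=(20.0, 9.0))

    @classmethod
    def human_default(cls) -> "RigGeometry":
        """28 x 28 cm work area (human rig)."""
        return cls(work_area_cm=(28.0, 28.0))

    def contains(self, points_cm: np.ndarray) -> np.ndarray:
        """Boolean mask: which screen points fall inside the work area."""
        p = np.asarray(points_cm, dtype=float)
        w, d = self.work_area_cm
        return (np.abs(p[..., 0]) <= w / 2) & (np.abs(p[..., 1]) <= d / 2)

    def to_dict(self) -> dict:
        return {
            "screen_origin_in_eye_frame": list(self.screen_origin_in_eye_frame),
            "work_area_cm": list(self.work_area_cm),
            "refresh_hz": self.screen_refresh_hz,
            "screen_extent_cm": self.screen_extent_cm,
            "reference_spot_positions": [list(p) for p in self.reference_spot_positions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigGeometry":
        return cls(
            screen_origin_in_eye_frame=tuple(d["screen_origin_in_eye_frame"]),
            work_area_cm=tuple(d["work_area_cm"]),
            screen_refresh_hz=float(d.get("refresh_hz", 60.0)),
            screen_extent_cm=float(d.get("screen_extent_cm", 30.0)),
            reference_spot_positions=tuple(
                tuple(p) for p in d.get("reference_spot_positions", ((-10.0, 4.5), (10.0, -4.5)))
            ),
        )


@dataclass(frozen=True)
class GazeAngles:
    """Gaze in polar visual-angle coordinates.

    ``rho`` is the eye-to-gaze-point distance in cm, ``theta`` the
    azimuth in degrees (0 = straight ahead along Y', positive right),
    ``phi`` the elevation in degrees from the horizontal X'Y' plane
    (negative = looking down).
    """

    rho: float
    theta: float
    phi: float


def _as_points(p, name: str = "points") -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape[-1] != 2:
        raise ValueError(f"{name} must have shape (..., 2), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def _as_vectors(u, name: str = "vectors") -> np.ndarray:
    a = np.asarray(u, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"{name} must have shape (..., 3), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def screen_to_eye_frame(points_cm, geometry: RigGeometry) -> np.ndarray:
    """Express screen-frame gaze points in the eye frame.

    A pure translation: the eye-frame coordinates of a point on the
    display plane are the screen coordinates plus the screen-origin
    offset ``o``.  Because the eye frame is centered on the eyeball, the
    result is also the gaze *vector* pointing from the eye to that point.

    Parameters
    ----------
    points_cm : (..., 2) array-like
        Screen-frame positions in cm.

    Returns
    -------
    (..., 3) ndarray of eye-frame coordinates, cm.
    """
    p = _as_points(points_cm)
    o = geometry.origin
    out = np.empty(p.shape[:-1] + (3,), dtype=float)
    out[..., 0] = p[..., 0] + o[0]
    out[..., 1] = p[..., 1] + o[1]
    out[..., 2] = o[2]
    return out


def eye_frame_to_screen(vectors, geometry: RigGeometry, *, atol: float = 1e-9) -> np.ndarray:
    """Inverse of :func:`screen_to_eye_frame` for points on the display plane."""
    u = _as_vectors(vectors)
    o = geometry.origin
    if not np.allclose(u[..., 2], o[2], atol=atol):
        raise ValueError("vectors do not lie on the display plane (Z' != o_z)")
    return u[..., :2] - o[:2]


def angular_distance(u, v) -> np.ndarray | float:
    """Visual angle in degrees between two gaze vectors.

    Equivalent to ``arccos(u.v / (|u||v|))`` but computed as
    ``atan2(|u x v|, u.v)``, which stays well conditioned for nearly
    parallel vectors (and returns exactly 0 for identical ones).
    Symmetric, in [0, 180].

    Raises
    ------
    ValueError
        If any vector has zero norm (degenerate gaze).
    """
    a = _as_vectors(u, "u")
    b = _as_vectors(v, "v")
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-norm gaze vector: angular distance undefined")
    cross = np.linalg.norm(np.cross(a, b), axis=-1)
    dot = np.sum(a * b, axis=-1)
    ang = np.degrees(np.arctan2(cross, dot))
    return ang if ang.ndim else float(ang)


def vector_to_polar(u, *, elevation_from_plane: bool = True):
    """Convert eye-frame gaze vectors to polar visual-angle coordinates.

    Returns ``(rho, theta, phi)`` with ``rho`` the vector norm in cm,
    ``theta`` the azimuth of the projection onto the horizontal X'Y'
    plane measured from Y' (straight ahead), and ``phi`` the elevation.

    With ``elevation_from_plane=True`` (default) ``phi`` is measured
    from the X'Y' plane, negative downward, so straight-ahead gaze is
    (0, 0).  With ``False`` the colatitude from the Z' (up) axis is
    returned instead.
    """
    a = _as_vectors(u)
    rho = np.linalg.norm(a, axis=-1)
    if np.any(rho == 0):
        raise ValueError("zero-norm gaze vector: polar angles undefined")
    theta = np.degrees(np.arctan2(a[..., 0], a[..., 1]))
    horiz = np.hypot(a[..., 0], a[..., 1])
    if elevation_from_plane:
        phi = np.degrees(np.arctan2(a[..., 2], horiz))
    else:
        phi = np.degrees(np.arctan2(horiz, a[..., 2]))
    if rho.ndim == 0:
        return float(rho), float(theta), float(phi)
    return rho, theta, phi


def polar_to_vector(rho, theta_deg, phi_deg, *, elevation_from_plane: bool = True) -> np.ndarray:
    """Inverse of :func:`vector_to_polar`."""
    rho = np.asarray(rho, dtype=float)
    th = np.radians(np.asarray(theta_deg, dtype=float))
    ph = np.radians(np.asarray(phi_deg, dtype=float))
    if elevation_from_plane:
        ch, sh = np.cos(ph), np.sin(ph)
    else:  # colatitude from Z'
        ch, sh = np.sin(ph), np.cos(ph)
    out = np.stack(
        [rho * ch * np.sin(th), rho * ch * np.cos(th), rho * sh],
        axis=-1,
    )
    return out


def screen_to_angles(points_cm, geometry: RigGeometry, *, elevation_from_plane: bool = True):
    """Screen-frame positions straight to polar visual angles."""
    return vector_to_polar(
        screen_to_eye_frame(points_cm, geometry),
        elevation_from_plane=elevation_from_plane,
    )


def angles_to_screen(theta_deg, phi_deg, geometry: RigGeometry) -> np.ndarray:
    """Intersect gaze directions (theta, phi) with the display plane.

    The gaze ray from the eyeball center along direction (theta, phi)
    is intersected with the plane ``Z' = o_z``; the intersection is
    returned in screen-frame cm.  Directions with non-negative
    elevation never hit the display plane and raise ``ValueError``.
    """
    d = polar_to_vector(1.0, theta_deg, phi_deg)
    dz = d[..., 2]
    if np.any(dz >= 0):
        raise ValueError("gaze direction does not intersect the display plane (phi >= 0)")
    o = geometry.origin
    t = o[2] / dz
    pts = d[..., :2] * t[..., None]
    return pts - o[:2]


def display_latency(
    vertical_distance_cm,
    geometry: RigGeometry,
    *,
    slope_ms_per_cm: float | None = None,
) -> np.ndarray | float:
    """Display latency (ms) at a given vertical distance from the reference spot.

    The display draws its image top to bottom, so the luminance change
    at a probe location lags the reference location linearly in their
    vertical separation (a space-time refresh model).  The default slope
    is ``frame_period / screen_extent``; a measured slope from a
    two-point photoresistor calibration can be passed instead.
    """
    d = np.asarray(vertical_distance_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("vertical distance must be non-negative")
    if slope_ms_per_cm is None:
        frame_period_ms = 1000.0 / geometry.screen_refresh_hz
        slope_ms_per_cm = frame_period_ms / geometry.screen_extent_cm
    out = slope_ms_per_cm * d
    return out if out.ndim else float(out)


def measured_latency_slope(probe_distance_cm: float, measured_latency_ms: float) -> float:
    """Slope (ms/cm) from a single reference/probe photoresistor measurement."""
    if probe_distance_cm <= 0:
        raise ValueError("probe distance must be positive")
    return measured_latency_ms / probe_distance_cm
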