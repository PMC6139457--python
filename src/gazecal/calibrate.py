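"""Build the volts -> cm inverse mapping from a fixation session.

The pipeline mirrors the empirical calibration procedure: clean each
fixation trial, average the retained voltages per target into anchors,
regrid the sparse anchor cloud in voltage space with a biharmonic
(Green's-function) spline, and fit bivariate polynomial surfaces
``x_cm = f1(X_v, Y_v)`` and ``y_cm = g1(X_v, Y_v)`` of total degree
2, 3 or 4 to the regridded surfaces (or directly to the anchors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .simulate import FixationSession, FixationTrial

__all__ = [
    "RejectionPolicy",
    "SampleSelection",
    "TargetVoltageAnchor",
    "BiharmonicSpline",
    "RegularizedMesh",
    "CalibrationModel",
    "UnusableTrialError",
    "MissingTargetError",
    "select_samples",
    "average_anchors",
    "regrid_biharmonic",
    "fit_polynomial",
    "calibrate_session",
    "compare_orders",
]


class UnusableTrialError(ValueError):
    """Raised when sample rejection leaves a trial with no usable samples."""


class MissingTargetError(ValueError):
    """Raised when one or more calibration targets have no usable trial."""

    def __init__(self, targets: list[tuple[float, float]]):
        self.targets = targets
        super().__init__(f"no usable trial for target(s): {targets}")


@dataclass(frozen=True)
class RejectionPolicy:
    """Conservative within-trial sample rejection.

    Samples are dropped if flagged invalid, outside the valid voltage
    range, or deviating from the trial median by more than
    ``robust_sd_multiple`` robust SDs (1.4826 * MAD) on either channel —
    a stand-in for online blink/saccade removal.
    """

    robust_sd_multiple: float = 5.0
    voltage_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.robust_sd_multiple <= 0:
            raise ValueError("robust_sd_multiple must be positive")


@dataclass
class SampleSelection:
    """Retained-sample mask plus a per-reason rejection report."""

    mask: np.ndarray  # (n,) bool
    n_total: int
    n_flagged_invalid: int
    n_out_of_range: int
    n_outlier: int

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())


def select_samples(
    trial: FixationTrial, policy: RejectionPolicy | None = None
) -> SampleSelection:
    """Clean one fixation trial; raise ``UnusableTrialError`` if nothing survives."""
    if len(trial) == 0:
        raise UnusableTrialError(f"trial {trial.trial_id} is empty")
    policy = policy or RejectionPolicy()
    v = trial.volts
    keep = trial.valid.copy()
    n_invalid = int((~keep).sum())
    if policy.voltage_range is not None:
        lo, hi = policy.voltage_range
        in_range = np.all((v >= lo) & (v <= hi), axis=1)
    else:
        in_range = np.all(np.isfinite(v), axis=1)
    n_range = int((keep & ~in_range).sum())
    keep &= in_range
    n_outlier = 0
    if keep.any():
        med = np.median(v[keep], axis=0)
        mad = np.median(np.abs(v[keep] - med), axis=0)
        robust_sd = 1.4826 * mad
        # floor at ADC scale so constant (noise-free) trials keep everything
        tol = policy.robust_sd_multiple * robust_sd + 1e-9
        inlier = np.all(np.abs(v - med) <= tol, axis=1)
        n_outlier = int((keep & ~inlier).sum())
        keep &= inlier
    if not keep.any():
        raise UnusableTrialError(
            f"trial {trial.trial_id}: all {len(trial)} samples rejected"
        )
    return SampleSelection(
        mask=keep,
        n_total=len(trial),
        n_flagged_invalid=n_invalid,
        n_out_of_range=n_range,
        n_outlier=n_outlier,
    )


@dataclass
class TargetVoltageAnchor:
    """Per-target mean voltage: one reference point of the inverse mapping."""

    target_cm: np.ndarray  # (2,)
    mean_voltage: np.ndarray  # (2,)
    n_samples: int
    dispersion_v: np.ndarray  # (2,) per-channel sample SD

    def __post_init__(self) -> None:
        self.target_cm = np.asarray(self.target_cm, dtype=float)
        self.mean_voltage = np.asarray(self.mean_voltage, dtype=float)
        self.dispersion_v = np.asarray(self.dispersion_v, dtype=float)
        if self.n_samples <= 0:
            raise ValueError("anchor requires n_samples > 0")
        if not np.all(np.isfinite(self.dispersion_v)):
            raise ValueError("anchor dispersion must be finite")


def average_anchors(
    session: FixationSession, policy: RejectionPolicy | None = None
) -> list[TargetVoltageAnchor]:
    """Average retained voltages per target across all repeats.

    Raises ``MissingTargetError`` naming every target left without a
    usable trial.
    """
    groups: dict[tuple[float, float], list[np.ndarray]] = {}
    for tr in session.trials:
        groups.setdefault((float(tr.target_cm[0]), float(tr.target_cm[1])), [])
    missing: list[tuple[float, float]] = []
    for tr in session.trials:
        key = (float(tr.target_cm[0]), float(tr.target_cm[1]))
        try:
            sel = select_samples(tr, policy)
        except UnusableTrialError:
            continue
        groups[key].append(tr.volts[sel.mask])
    anchors: list[TargetVoltageAnchor] = []
    for key, chunks in groups.items():
        if not chunks:
            missing.append(key)
            continue
        v = np.vstack(chunks)
        anchors.append(
            TargetVoltageAnchor(
                target_cm=np.array(key),
                mean_voltage=v.mean(axis=0),
                n_samples=len(v),
                dispersion_v=v.std(axis=0, ddof=1) if len(v) > 1 else np.zeros(2),
            )
        )
    if missing:
        raise MissingTargetError(missing)
    return anchors


class BiharmonicSpline:
    """2-D biharmonic Green's-function interpolant with an affine term.

    The surface is ``s(q) = sum_j w_j * g(|q - q_j|) + b0 + b1*q_x + b2*q_y``
    with ``g(r) = r^2 (ln r - 1)`` (the Green's function of the biharmonic
    operator in the plane) and side conditions forcing the weights to be
    orthogonal to affine functions.  It passes through every data point
    and reproduces affine data exactly.  Centers are scaled to a unit box
    internally for conditioning.
    """

    def __init__(self, points: np.ndarray, values: np.ndarray):
        points = np.asarray(points, dtype=float)
        values = np.asarray(values, dtype=float)
        if points.ndim != 2 or points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        n = len(points)
        if n < 6:
            raise ValueError("need at least 6 anchors for biharmonic regridding")
        # duplicate centers make the interpolation system singular
        _, inverse, counts = np.unique(
            points.round(12), axis=0, return_inverse=True, return_counts=True
        )
        if np.any(counts > 1):
            dup_idx = np.nonzero(counts[inverse] > 1)[0]
            dups = [tuple(points[i]) for i in dup_idx]
            raise ValueError(f"duplicate anchors make the system singular: {dups}")
        # non-collinearity: the affine block must have full column rank
        centered = points - points.mean(axis=0)
        if np.linalg.matrix_rank(centered) < 2:
            raise ValueError("anchors are collinear; surface is underdetermined")
        self._center = points.mean(axis=0)
        self._scale = np.maximum(np.ptp(points, axis=0) / 2.0, 1e-12)
        q = (points - self._center) / self._scale
        G = self._green(q, q)
        P = np.column_stack([np.ones(n), q])
        A = np.zeros((n + 3, n + 3))
        A[:n, :n] = G
        A[:n, n:] = P
        A[n:, :n] = P.T
        rhs = np.concatenate([values, np.zeros(3)])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as e:  # pragma: no cover - guarded above
            raise ValueError(f"singular biharmonic system: {e}") from e
        self._q = q
        self._w = sol[:n]
        self._b = sol[n:]

    @staticmethod
    def _green(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d = a[:, None, :] - b[None, :, :]
        r = np.sqrt(np.sum(d * d, axis=-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            g = r * r * (np.log(r) - 1.0)
        g[r == 0] = 0.0
        return g

    def __call__(self, query: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(query, dtype=float))
        qs = (q - self._center) / self._scale
        G = self._green(qs, self._q)
        vals = G @ self._w + self._b[0] + qs @ self._b[1:]
        return vals if np.asarray(query).ndim > 1 else float(vals[0])


@dataclass
class RegularizedMesh:
    """Biharmonic surfaces evaluated on a regular lattice in voltage space."""

    grid_xv: np.ndarray  # (res,)
    grid_yv: np.ndarray  # (res,)
    values_x_cm: np.ndarray  # (res, res), f1 surface
    values_y_cm: np.ndarray  # (res, res), g1 surface
    anchors: list[TargetVoltageAnchor]

    @property
    def nodes(self) -> np.ndarray:
        gx, gy = np.meshgrid(self.grid_xv, self.grid_yv)
        return np.column_stack([gx.ravel(), gy.ravel()])


def regrid_biharmonic(
    anchors: list[TargetVoltageAnchor], resolution: int = 50
) -> RegularizedMesh:
    """Resample the sparse voltage-space anchors onto a regular lattice.

    The axis change from (cm -> volts) to (volts -> cm) leaves the anchor
    cloud irregular in voltage space; a biharmonic spline through the
    anchors gives smooth ``f1``/``g1`` surfaces on the lattice covering
    the anchors' voltage bounding box.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    volts = np.array([a.mean_voltage for a in anchors])
    x_cm = np.array([a.target_cm[0] for a in anchors])
    y_cm = np.array([a.target_cm[1] for a in anchors])
    sx = BiharmonicSpline(volts, x_cm)
    sy = BiharmonicSpline(volts, y_cm)
    gx = np.linspace(volts[:, 0].min(), volts[:, 0].max(), resolution)
    gy = np.linspace(volts[:, 1].min(), volts[:, 1].max(), resolution)
    mx, my = np.meshgrid(gx, gy)
    nodes = np.column_stack([mx.ravel(), my.ravel()])
    vx = sx(nodes).reshape(resolution, resolution)
    vy = sy(nodes).reshape(resolution, resolution)
    return RegularizedMesh(gx, gy, vx, vy, list(anchors))


def _basis_exponents(order: int) -> list[tuple[int, int]]:
    """Full bivariate basis of total degree <= order (6/10/15 terms)."""
    return [(i, j) for d in range(order + 1) for i in range(d, -1, -1) for j in [d - i]]


def _design_matrix(volts_norm: np.ndarray, exponents) -> np.ndarray:
    u, v = volts_norm[:, 0], volts_norm[:, 1]
    return np.column_stack([u**i * v**j for i, j in exponents])


@dataclass
class CalibrationModel:
    """Fitted bivariate polynomial surfaces f1, g1 (volts -> screen cm).

    Voltages are affinely normalized to [-1, 1] per channel (stored in
    the model) before the polynomial is evaluated, to keep the quartic
    design matrix well conditioned.  Evaluation outside the fitting
    voltage box is flagged as extrapolation, never rejected.
    """

    order: int
    exponents: list[tuple[int, int]]
    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    norm_center: np.ndarray  # (2,)
    norm_halfwidth: np.ndarray  # (2,)
    valid_voltage_box: tuple[np.ndarray, np.ndarray]  # (lo(2,), hi(2,))
    fit_residuals_cm: np.ndarray  # (n_anchors, 2)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (self.order + 1) * (self.order + 2) // 2
        if len(self.exponents) != expected or len(self.coeffs_x) != expected:
            raise ValueError(
                f"order-{self.order} model needs {expected} coefficients, "
                f"got {len(self.coeffs_x)}"
            )
        if not np.all(np.isfinite(self.fit_residuals_cm)):
            raise ValueError("fit residuals must be finite")

    def _normalize(self, volts: np.ndarray) -> np.ndarray:
        return (volts - self.norm_center) / self.norm_halfwidth

    def predict(self, volts) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate f1/g1 at raw voltages.

        Returns ``(points_cm, extrapolated)``; non-finite voltage rows
        yield NaN points flagged as extrapolated rather than raising, to
        honor the streaming contract.
        """
        v = np.atleast_2d(np.asarray(volts, dtype=float))
        finite = np.all(np.isfinite(v), axis=1)
        out = np.full((len(v), 2), np.nan)
        lo, hi = self.valid_voltage_box
        extrap = ~finite | np.any((v < lo) | (v > hi), axis=1)
        if finite.any():
            X = _design_matrix(self._normalize(v[finite]), self.exponents)
            out[finite, 0] = X @ self.coeffs_x
            out[finite, 1] = X @ self.coeffs_y
        if np.asarray(volts).ndim == 1:
            return out[0], bool(extrap[0])
        return out, extrap

    @property
    def rms_residual_cm(self) -> float:
        return float(np.sqrt(np.mean(np.sum(self.fit_residuals_cm**2, axis=1))))

    # ---- JSON serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "basis": "total_degree",
            "coeffs_x": {f"c_{i}{j}": c for (i, j), c in zip(self.exponents, self.coeffs_x)},
            "coeffs_y": {f"c_{i}{j}": c for (i, j), c in zip(self.exponents, self.coeffs_y)},
            "normalization": {
                "center_v": list(self.norm_center),
                "halfwidth_v": list(self.norm_halfwidth),
            },
            "valid_voltage_box": {
                "lo_v": list(self.valid_voltage_box[0]),
                "hi_v": list(self.valid_voltage_box[1]),
            },
            "fit_residuals_cm": self.fit_residuals_cm.tolist(),
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        from .session_io import atomic_write_text

        atomic_write_text(path, json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        order = int(d["order"])
        exponents = _basis_exponents(order)
        cx = np.array([d["coeffs_x"][f"c_{i}{j}"] for i, j in exponents])
        cy = np.array([d["coeffs_y"][f"c_{i}{j}"] for i, j in exponents])
        return cls(
            order=order,
            exponents=exponents,
            coeffs_x=cx,
            coeffs_y=cy,
            norm_center=np.array(d["normalization"]["center_v"]),
            norm_halfwidth=np.array(d["normalization"]["halfwidth_v"]),
            valid_voltage_box=(
                np.array(d["valid_voltage_box"]["lo_v"]),
                np.array(d["valid_voltage_box"]["hi_v"]),
            ),
            fit_residuals_cm=np.array(d["fit_residuals_cm"]),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as f:
            return cls.from_dict(json.load(f))


def fit_polynomial(
    data: RegularizedMesh | list[TargetVoltageAnchor],
    order: int = 4,
    *,
    provenance: dict | None = None,
) -> CalibrationModel:
    """Least-squares fit of the f1/g1 polynomial pair.

    ``data`` may be a :class:`RegularizedMesh` (fit on the regridded
    surfaces, the default pipeline) or the raw anchor list (fit directly
    on the 25 reference points).  Residuals are always reported at the
    anchors, in cm.
    """
    if order not in (2, 3, 4):
        raise ValueError(f"polynomial order must be 2, 3 or 4, got {order}")
    if isinstance(data, RegularizedMesh):
        pts_v = data.nodes
        vals_x = data.values_x_cm.ravel()
        vals_y = data.values_y_cm.ravel()
        anchors = data.anchors
        fit_on = "mesh"
    else:
        anchors = list(data)
        pts_v = np.array([a.mean_voltage for a in anchors])
        vals_x = np.array([a.target_cm[0] for a in anchors])
        vals_y = np.array([a.target_cm[1] for a in anchors])
        fit_on = "anchors"
    exponents = _basis_exponents(order)
    if len(pts_v) < len(exponents):
        raise ValueError(
            f"need at least {len(exponents)} points for an order-{order} fit, got {len(pts_v)}"
        )
    center = (pts_v.max(axis=0) + pts_v.min(axis=0)) / 2.0
    halfwidth = np.maximum((pts_v.max(axis=0) - pts_v.min(axis=0)) / 2.0, 1e-12)
    X = _design_matrix((pts_v - center) / halfwidth, exponents)
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise ValueError(f"rank-deficient polynomial design matrix (cond={cond:.3g})")
    cx, *_ = np.linalg.lstsq(X, vals_x, rcond=None)
    cy, *_ = np.linalg.lstsq(X, vals_y, rcond=None)
    anchor_v = np.array([a.mean_voltage for a in anchors])
    anchor_cm = np.array([a.target_cm for a in anchors])
    Xa = _design_matrix((anchor_v - center) / halfwidth, exponents)
    pred = np.column_stack([Xa @ cx, Xa @ cy])
    residuals = pred - anchor_cm
    prov = {"fit_on": fit_on, "n_points": int(len(pts_v)), "design_cond": float(cond)}
    if provenance:
        prov.update(provenance)
    return CalibrationModel(
        order=order,
        exponents=exponents,
        coeffs_x=cx,
        coeffs_y=cy,
        norm_center=center,
        norm_halfwidth=halfwidth,
        valid_voltage_box=(anchor_v.min(axis=0), anchor_v.max(axis=0)),
        fit_residuals_cm=residuals,
        provenance=prov,
    )


def calibrate_session(
    session: FixationSession,
    *,
    order: int = 4,
    fit_on: str = "mesh",
    regrid_resolution: int = 50,
    policy: RejectionPolicy | None = None,
) -> CalibrationModel:
    """Full calibration pipeline: select, average, regrid, fit."""
    anchors = average_anchors(session, policy)
    if fit_on == "mesh":
        data: RegularizedMesh | list[TargetVoltageAnchor] = regrid_biharmonic(
            anchors, regrid_resolution
        )
    elif fit_on == "anchors":
        data = anchors
    else:
        raise ValueError(f"fit_on must be 'mesh' or 'anchors', got {fit_on!r}")
    prov = {"session": dict(session.provenance), "regrid_resolution": regrid_resolution}
    return fit_polynomial(data, order, provenance=prov)


@dataclass
class OrderComparison:
    """Per-order validation accuracies and pairwise paired t-tests."""

    orders: list[int]
    per_trial_errors_deg: dict[int, np.ndarray]
    mean_error_deg: dict[int, float]
    median_error_deg: dict[int, float]
    paired_t_p: dict[tuple[int, int], float]


def compare_orders(
    models: list[CalibrationModel],
    validation_session: FixationSession,
    *,
    policy: RejectionPolicy | None = None,
) -> OrderComparison:
    """Compare calibration models on a shared validation session.

    Every model reconstructs the same per-trial mean fixation; per-trial
    angular distances to target are compared with paired t-tests for
    each model pair.
    """
    from scipy import stats

    from .reconstruct import fixation_errors

    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    errors: dict[int, np.ndarray] = {}
    trial_ids: list[np.ndarray] = []
    for m in models:
        tab = fixation_errors(validation_session, m, policy=policy)
        errors[m.order] = tab["angular_error_deg"].to_numpy()
        trial_ids.append(tab["trial_id"].to_numpy())
    if any(not np.array_equal(trial_ids[0], ids) for ids in trial_ids[1:]):
        raise ValueError("models were evaluated on mismatched trial sets")
    orders = [m.order for m in models]
    paired: dict[tuple[int, int], float] = {}
    for i in range(len(orders)):
        for j in range(i + 1, len(orders)):
            a, b = errors[orders[i]], errors[orders[j]]
            if np.array_equal(a, b):
                p = 1.0
            else:
                p = float(stats.ttest_rel(a, b).pvalue)
            paired[(orders[i], orders[j])] = p
    return OrderComparison(
        orders=orders,
        per_trial_errors_deg=errors,
        mean_error_deg={k: float(v.mean()) for k, v in errors.items()},
        median_error_deg={k: float(np.median(v)) for k, v in errors.items()},
        paired_t_p=paired,
    )
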