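"""Validation battery for the gaze reconstruction.

Accuracy is the median absolute angular distance to target across
trials; precision is reported two ways: the interquartile range of the
angular-error distribution across trials, and the sample-to-sample RMS
of angular distances between successive samples of a single fixation
(the Holmqvist-style tracker-noise measure).  A rank-sum comparison and
a discriminability table (shifted voltage distributions pushed through
the reconstruction, then t- and F-tested on theta/phi) complete the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .calibrate import CalibrationModel
from .geometry import RigGeometry, angular_distance
from .reconstruct import gaze_to_angles, voltages_to_gaze

__all__ = [
    "accuracy",
    "precision_iqr",
    "precision_rms",
    "compare_distributions",
    "f_test_variance",
    "shift_boundaries",
    "discriminability_table",
    "MetricsReport",
    "metrics_report",
]


def _errors(errors) -> np.ndarray:
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error set")
    if not np.all(np.isfinite(e)):
        raise ValueError("error set contains non-finite values")
    return e


def accuracy(errors_deg) -> float:
    """Median of the absolute angular distances to target (degrees)."""
    return float(np.median(np.abs(_errors(errors_deg))))


def precision_iqr(errors_deg) -> float:
    """Interquartile range of the angular-error distribution (degrees).

    Quantiles use the linear-interpolation convention.
    """
    e = _errors(errors_deg)
    q1, q3 = np.percentile(e, [25, 75], method="linear")
    return float(q3 - q1)


def precision_rms(gaze_vectors) -> float:
    """RMS of angular distances between successive fixation samples (degrees).

    ``gaze_vectors`` are eye-frame gaze vectors (n >= 2, shape (n, 3))
    recorded during a single fixation trial.
    """
    u = np.asarray(gaze_vectors, dtype=float)
    if u.ndim != 2 or u.shape[1] != 3:
        raise ValueError("gaze_vectors must have shape (n, 3)")
    if len(u) < 2:
        raise ValueError("precision_rms needs at least 2 samples")
    d = angular_distance(u[:-1], u[1:])
    return float(np.sqrt(np.mean(np.square(d))))


def compare_distributions(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two error sets."""
    a = _errors(a)
    b = _errors(b)
    return float(stats.ranksums(a, b).pvalue)


def f_test_variance(a, b) -> float:
    """Two-sided variance-ratio (Fisher) test p-value."""
    a = _errors(a)
    b = _errors(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    F = va / vb if vb > 0 else np.inf
    dfa, dfb = len(a) - 1, len(b) - 1
    p_low = stats.f.cdf(F, dfa, dfb)
    p_high = stats.f.sf(F, dfa, dfb)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def shift_boundaries(sigma_v: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Bracketing mean shifts around the t-test significance boundary.

    Locates (numerically) the mean shift of a normal distribution with
    per-sample SD ``sigma_v`` at which the *expected* two-sample
    t statistic (two groups of ``n``) crosses the ``alpha`` critical
    value, then returns the pair ``(boundary - sigma/20, boundary +
    sigma/20)``: the maximal shift that stays non-significant and the
    minimal shift that becomes significant.  The two differ by a tenth
    of the distribution's standard deviation.
    """
    if sigma_v <= 0:
        raise ValueError("sigma must be positive")
    if n < 2:
        raise ValueError("n must be >= 2")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=2 * n - 2)
    se = sigma_v * np.sqrt(2.0 / n)

    def expected_t_minus_crit(s: float) -> float:
        return s / se - t_crit

    hi = 10.0 * sigma_v
    boundary = optimize.brentq(expected_t_minus_crit, 0.0, hi, xtol=1e-12 * sigma_v)
    return boundary - sigma_v / 20.0, boundary + sigma_v / 20.0


def discriminability_table(
    model: CalibrationModel,
    geometry: RigGeometry,
    eye_mean_v,
    eye_sd_v,
    *,
    n: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Does the reconstruction preserve eye-position discriminability?

    A normal voltage distribution (``n`` samples, per-channel mean/SD
    from a center-target fixation) is drawn once, then translated along
    each voltage axis by the maximal-non-significant and the
    minimal-significant shifts from :func:`shift_boundaries`.  Original
    and shifted sets are pushed through the gaze reconstruction and the
    visual-angle conversion; Student t-tests (means) and Fisher F-tests
    (shape) are run on theta and phi between each shifted set and the
    original.  Rows follow the conventional report layout: a
    "different eye position distributions" block (min-significant
    shifts) and a "same" block (max-non-significant shifts), each with a
    Shift X and a Shift Y row.
    """
    eye_mean = np.asarray(eye_mean_v, dtype=float)
    eye_sd = np.asarray(eye_sd_v, dtype=float)
    if np.any(eye_sd <= 0):
        raise ValueError("eye position SD must be positive on both channels")
    rng = np.random.default_rng(seed)
    base = rng.normal(eye_mean, eye_sd, size=(n, 2))

    def to_angles(volts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts, _ = voltages_to_gaze(volts, model)
        _, theta, phi = gaze_to_angles(pts, geometry)
        return theta, phi

    th0, ph0 = to_angles(base)
    rows = []
    axis_names = {0: "Shift X", 1: "Shift Y"}
    for block, which in (("different", 1), ("same", 0)):
        for axis in (0, 1):
            lo_hi = shift_boundaries(float(eye_sd[axis]), n, alpha)
            shift = lo_hi[which]
            shifted = base.copy()
            shifted[:, axis] += shift
            th, ph = to_angles(shifted)
            rows.append(
                {
                    "block": (
                        "different eye position distributions"
                        if block == "different"
                        else "same eye position distributions"
                    ),
                    "shift": axis_names[axis],
                    "shift_v": shift,
                    "t_test_theta_p": float(stats.ttest_ind(th, th0).pvalue),
                    "t_test_phi_p": float(stats.ttest_ind(ph, ph0).pvalue),
                    "f_test_theta_p": f_test_variance(th, th0),
                    "f_test_phi_p": f_test_variance(ph, ph0),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MetricsReport:
    """Accuracy/precision summary of a validation error set."""

    accuracy_deg: float
    precision_iqr_deg: float
    n_trials: int
    precision_rms_deg: float | None = None
    per_target: pd.DataFrame | None = None
    quantile_rule: str = "linear"

    def to_dict(self) -> dict:
        d = {
            "accuracy_deg": self.accuracy_deg,
            "precision_iqr_deg": self.precision_iqr_deg,
            "n_trials": self.n_trials,
            "quantile_rule": self.quantile_rule,
        }
        if self.precision_rms_deg is not None:
            d["precision_rms_deg"] = self.precision_rms_deg
        if self.per_target is not None:
            d["per_target"] = self.per_target.to_dict(orient="records")
        return d


def metrics_report(error_table: pd.DataFrame, *, precision_rms_deg: float | None = None) -> MetricsReport:
    """Summarize a per-trial error table from ``fixation_errors``."""
    e = error_table["angular_error_deg"].to_numpy()
    per_target = (
        error_table.groupby(["target_x_cm", "target_y_cm"])["angular_error_deg"]
        .agg(["median", "count"])
        .reset_index()
        .rename(columns={"median": "median_error_deg", "count": "n_trials"})
    )
    return MetricsReport(
        accuracy_deg=accuracy(e),
        precision_iqr_deg=precision_iqr(e),
        n_trials=len(e),
        precision_rms_deg=precision_rms_deg,
        per_target=per_target,
    )
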