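"""Session file format: a commented JSON header plus a CSV sample table.

Header lines start with ``#``; the ``# meta:`` line carries the rig
geometry, sampling rate, units declaration and generator provenance.
The body has one row per sample: ``trial_id, target_x_cm, target_y_cm,
t_ms, xv_volts, yv_volts, valid``.  All coordinates are screen-frame cm
with the origin at the work-area center, y increasing away from the
body.  Writes are atomic (temp file then rename).
"""

from __future__ import annotations

import io
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import RigGeometry
from .simulate import FixationSession, FixationTrial

__all__ = ["read_session", "write_session", "session_to_frame", "atomic_write_text"]

FORMAT_TAG = "gazecal-session v1"
REQUIRED_COLUMNS = [
    "trial_id",
    "target_x_cm",
    "target_y_cm",
    "t_ms",
    "xv_volts",
    "yv_volts",
    "valid",
]
UNITS = {"position": "cm", "voltage": "volts", "time": "ms"}


class SessionFormatError(ValueError):
    """Malformed session file (bad header, units, columns or timestamps)."""


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename in the same directory."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as f:
            f.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def session_to_frame(session: FixationSession) -> pd.DataFrame:
    rows = []
    for tr in session.trials:
        rows.append(
            pd.DataFrame(
                {
                    "trial_id": tr.trial_id,
                    "target_x_cm": tr.target_cm[0],
                    "target_y_cm": tr.target_cm[1],
                    "t_ms": tr.t_ms,
                    "xv_volts": tr.volts[:, 0],
                    "yv_volts": tr.volts[:, 1],
                    "valid": tr.valid.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_session(session: FixationSession, path) -> None:
    """Serialize a session to the commented-header CSV format (atomic)."""
    meta = {
        "format": FORMAT_TAG,
        "units": UNITS,
        "rate_hz": session.rate_hz,
        "geometry": session.geometry.to_dict(),
        "provenance": session.provenance,
    }
    frame = session_to_frame(session)
    buf = io.StringIO()
    buf.write(f"# {FORMAT_TAG}\n")
    buf.write(f"# meta: {json.dumps(meta)}\n")
    # full float precision so write/read round-trips are lossless
    frame.to_csv(buf, index=False, float_format="%.17g")
    atomic_write_text(path, buf.getvalue())


def read_session(path) -> FixationSession:
    """Parse a session file, validating units, columns and timestamps."""
    path = Path(path)
    meta = None
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("meta:"):
                try:
                    meta = json.loads(body[len("meta:") :])
                except json.JSONDecodeError as e:
                    raise SessionFormatError(f"{path}:{lineno}: unparseable meta header: {e}")
    if meta is None:
        raise SessionFormatError(f"{path}: missing '# meta:' header line")
    if meta.get("units") != UNITS:
        raise SessionFormatError(
            f"{path}: unit declaration must be {UNITS}, got {meta.get('units')}"
        )
    rate = float(meta.get("rate_hz", 0))
    if rate <= 0:
        raise SessionFormatError(f"{path}: sampling rate must be > 0, got {rate}")
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as e:
        raise SessionFormatError(f"{path}: malformed CSV body: {e}")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing required column(s) {missing}")
    bad = frame[REQUIRED_COLUMNS[:-1]].isna().any(axis=1)
    if bad.any():
        # +3 for the two header lines and the column row (1-based)
        lines = [int(i) + 3 for i in frame.index[bad][:10]]
        raise SessionFormatError(f"{path}: malformed rows at line(s) {lines}")
    geometry = RigGeometry.from_dict(meta["geometry"])
    trials: list[FixationTrial] = []
    for tid, g in frame.groupby("trial_id", sort=True):
        t_ms = g["t_ms"].to_numpy(dtype=float)
        if len(t_ms) > 1 and not np.all(np.diff(t_ms) > 0):
            raise SessionFormatError(
                f"{path}: trial {tid}: timestamps not strictly increasing"
            )
        target = np.array([g["target_x_cm"].iloc[0], g["target_y_cm"].iloc[0]])
        volts = g[["xv_volts", "yv_volts"]].to_numpy(dtype=float)
        valid = g["valid"].to_numpy().astype(bool)
        trials.append(FixationTrial(int(tid), target, t_ms, volts, valid))
    return FixationSession(
        trials, geometry, rate_hz=rate, provenance=meta.get("provenance", {})
    )
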