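"""CSV interchange for gaze series and event lists.

Gaze schema: ``t,x[,y][,blink]`` — time in seconds, angles in degrees,
blink 0/1.  Event schema:
``onset_s,offset_s,onset_idx,offset_idx,amplitude_deg,peak_velocity_deg_s,duration_s``.
Floats are written with 17 significant digits so files round-trip
bit-identically.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GazeTimeSeries, SaccadeEvent

__all__ = ["read_gaze_csv", "write_gaze_csv", "read_events_csv", "write_events_csv"]

_EVENT_COLS = ["onset_s", "offset_s", "onset_idx", "offset_idx",
               "amplitude_deg", "peak_velocity_deg_s", "duration_s"]


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


def read_gaze_csv(path, sampling_rate: float | None = None) -> GazeTimeSeries:
    """Read a gaze CSV; infer the sampling rate when not given.

    Errors name the offending data line (1-based, header is line 1).
    Inferred rates warn-free only when timestamp jitter is below 1 ppm of
    the sample interval — larger jitter raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t", "x"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["t"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(t))
    if bad.size:
        raise ValueError(f"{path}: unparseable time at line {bad[0] + 2}")
    dt = np.diff(t)
    nonpos = np.flatnonzero(dt <= 0)
    if nonpos.size:
        raise ValueError(
            f"{path}: non-increasing time at line {nonpos[0] + 3}")
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(dt)) if len(dt) else 1.0
    blink = None
    if "blink" in df.columns:
        blink = df["blink"].to_numpy(dtype=float) > 0.5
    return GazeTimeSeries(
        t=t, x=df["x"].to_numpy(dtype=float), sampling_rate=sampling_rate,
        y=df["y"].to_numpy(dtype=float) if "y" in df.columns else None,
        blink_mask=blink)


def write_gaze_csv(g: GazeTimeSeries, path) -> None:
    path = Path(path)
    cols = ["t", "x"] + (["y"] if g.y is not None else [])
    has_blink = g.blink_mask is not None
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols + (["blink"] if has_blink else []))
        for i in range(len(g)):
            row = [_fmt(g.t[i]), _fmt(g.x[i])]
            if g.y is not None:
                row.append(_fmt(g.y[i]))
            if has_blink:
                row.append("1" if g.blink_mask[i] else "0")
            w.writerow(row)


def write_events_csv(events: list[SaccadeEvent], path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_EVENT_COLS)
        for e in events:
            w.writerow([_fmt(e.onset_s), _fmt(e.offset_s),
                        str(e.onset_idx), str(e.offset_idx),
                        _fmt(e.amplitude), _fmt(e.peak_velocity),
                        _fmt(e.duration)])


def read_events_csv(path) -> list[SaccadeEvent]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _EVENT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    events = []
    for k, row in df.iterrows():
        try:
            events.append(SaccadeEvent(
                onset_idx=int(row["onset_idx"]), offset_idx=int(row["offset_idx"]),
                onset_s=float(row["onset_s"]), offset_s=float(row["offset_s"]),
                amplitude=float(row["amplitude_deg"]),
                peak_velocity=float(row["peak_velocity_deg_s"]),
                duration=float(row["duration_s"])))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: invalid event at line {k + 2}: {exc}") from exc
    return events
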