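"""Reference baseline detectors: velocity thresholding and dispersion thresholding.

Both operate on the raw (not denoised) series and pass through the same
post-processing rules as the proposed detector so comparisons are fair.
They exist to quantify what the denoising step buys; their parameters are
classical defaults, not tuned values.
"""

from __future__ import annotations

import numpy as np

from .core import GazeTimeSeries, SaccadeEvent
from .detect import combined_speed, postprocess

__all__ = ["vt_detect", "dt_detect"]


def _runs_to_events(mask: np.ndarray, speed: np.ndarray, fs: float) -> list[SaccadeEvent]:
    """Contiguous True runs of ``mask`` as half-open pre-filter events."""
    n = len(mask)
    edges = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(n)
    events = []
    for s, e in zip(starts, ends):
        pk = float(speed[s:e].max())
        if pk <= 0:
            continue
        events.append(SaccadeEvent(
            onset_idx=s, offset_idx=e, onset_s=s / fs, offset_s=e / fs,
            amplitude=0.0, peak_velocity=pk, duration=(e - s) / fs,
            truncated=(e == n)))
    return events


def vt_detect(g: GazeTimeSeries, threshold: float = 30.0) -> list[SaccadeEvent]:
    """Fixed velocity thresholding on the raw central-difference speed.

    Samples faster than ``threshold`` deg/s are saccadic; contiguous runs
    become events.  No hysteresis, no denoising.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fs = g.sampling_rate
    speed = combined_speed(g.channels, fs)
    events = _runs_to_events(speed > threshold, speed, fs)
    return postprocess(events, g, speed=speed)


def dt_detect(
    g: GazeTimeSeries,
    dispersion_threshold: float = 1.0,
    window: float = 0.1,
) -> list[SaccadeEvent]:
    """Dispersion thresholding (I-DT): fixations are low-dispersion windows.

    A window (initially ``window`` seconds) whose dispersion — per-channel
    (max - min), summed — stays below ``dispersion_threshold`` deg is
    grown into a fixation; everything between fixations is a saccade.
    Defaults are the classical 1 deg / 100 ms convention.
    """
    fs = g.sampling_rate
    n = len(g)
    w = int(round(window * fs))
    if w < 2:
        raise ValueError("window must cover at least 2 samples")
    if w > n:
        raise ValueError("window longer than the record")
    chans = g.channels

    def dispersion(s: int, e: int) -> float:
        return float(sum(ch[s:e].max() - ch[s:e].min() for ch in chans))

    is_fixation = np.zeros(n, dtype=bool)
    s = 0
    while s + w <= n:
        if dispersion(s, s + w) <= dispersion_threshold:
            e = s + w
            while e < n and dispersion(s, e + 1) <= dispersion_threshold:
                e += 1
            is_fixation[s:e] = True
            s = e
        else:
            s += 1

    speed = combined_speed(chans, fs)
    events = _runs_to_events(~is_fixation, speed, fs)
    return postprocess(events, g, speed=speed)
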