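"""Saccade detection on denoised eye-position series.

Detection is plain velocity thresholding with hysteresis: an event opens
when eye speed exceeds 30 deg/s and closes when it falls below 10 deg/s.
The lower closing threshold reflects the asymmetry of saccadic velocity
profiles (high acceleration, lower deceleration), and matters especially
for slow saccades whose tails would otherwise be clipped.  Four
post-processing rules remove implausible detections: proximity to a blink
(< 10 samples), merging of events closer than 40 ms (post-saccadic
oscillations are not separate saccades), a 12 ms minimum duration, and an
800 deg/s physiological cap on peak velocity.
"""

from __future__ import annotations

import numpy as np

from .core import GazeTimeSeries, SaccadeEvent

__all__ = ["ONSET_THRESHOLD", "OFFSET_THRESHOLD", "central_velocity",
           "combined_speed", "threshold_events", "postprocess", "detect_saccades"]

ONSET_THRESHOLD = 30.0       # deg/s, opens an event
OFFSET_THRESHOLD = 10.0      # deg/s, closes an event
MIN_DURATION_S = 0.012       # s
MIN_ISI_S = 0.040            # s, events closer than this are merged
MAX_PEAK_VELOCITY = 800.0    # deg/s, physiological plausibility cap
BLINK_MARGIN_SAMPLES = 10    # samples


def central_velocity(x: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Velocity by the central-difference filter [0.5, 0, -0.5], deg/s.

    Endpoints use one-sided differences.  Exact for linear signals.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    v = np.empty_like(x)
    v[1:-1] = 0.5 * (x[2:] - x[:-2]) * sampling_rate
    v[0] = (x[1] - x[0]) * sampling_rate
    v[-1] = (x[-1] - x[-2]) * sampling_rate
    return v


def combined_speed(channels: list[np.ndarray], sampling_rate: float) -> np.ndarray:
    """Eye speed: |v| for one channel, Euclidean norm for two."""
    vs = [central_velocity(ch, sampling_rate) for ch in channels]
    if len(vs) == 1:
        return np.abs(vs[0])
    return np.hypot(vs[0], vs[1])


def threshold_events(
    v: np.ndarray,
    sampling_rate: float,
    onset_threshold: float = ONSET_THRESHOLD,
    offset_threshold: float = OFFSET_THRESHOLD,
) -> list[SaccadeEvent]:
    """Hysteresis thresholding of a non-negative speed series.

    An event opens at the first sample with speed > ``onset_threshold``
    outside an open event and closes at the first subsequent sample with
    speed < ``offset_threshold`` (excluded from the half-open interval).
    An event still open at the end of the series closes at the last
    sample and is flagged ``truncated``.  Amplitudes are filled in later
    by :func:`postprocess`; here they are 0.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("speed must be non-negative")
    n = len(v)
    opens = np.flatnonzero(v > onset_threshold)
    closes = np.flatnonzero(v < offset_threshold)
    events: list[SaccadeEvent] = []
    pos = 0
    while True:
        k = np.searchsorted(opens, pos)
        if k == len(opens):
            break
        onset = int(opens[k])
        m = np.searchsorted(closes, onset)
        if m == len(closes):
            offset, truncated = n, True
        else:
            offset, truncated = int(closes[m]), False
        events.append(SaccadeEvent(
            onset_idx=onset, offset_idx=offset,
            onset_s=onset / sampling_rate, offset_s=offset / sampling_rate,
            amplitude=0.0, peak_velocity=float(v[onset:offset].max()),
            duration=(offset - onset) / sampling_rate, truncated=truncated))
        if truncated:
            break
        pos = offset + 1
    return events


def _remeasure(ev: SaccadeEvent, g: GazeTimeSeries, speed: np.ndarray) -> SaccadeEvent:
    """Recompute amplitude and peak velocity of an event from a trace."""
    n = len(g)
    i, j = ev.onset_idx, min(ev.offset_idx, n)
    e_in = min(j, n - 1)
    disp = [ch[e_in] - ch[i] for ch in g.channels]
    amp = float(np.hypot(*disp)) if len(disp) == 2 else abs(float(disp[0]))
    return SaccadeEvent(
        onset_idx=i, offset_idx=j,
        onset_s=i / g.sampling_rate, offset_s=j / g.sampling_rate,
        amplitude=amp, peak_velocity=float(speed[i:j].max()),
        duration=(j - i) / g.sampling_rate, truncated=ev.truncated)


def postprocess(
    events: list[SaccadeEvent],
    g: GazeTimeSeries,
    speed: np.ndarray | None = None,
    min_duration_s: float = MIN_DURATION_S,
    min_isi_s: float = MIN_ISI_S,
    max_peak_velocity: float = MAX_PEAK_VELOCITY,
    blink_margin: int = BLINK_MARGIN_SAMPLES,
) -> list[SaccadeEvent]:
    """Apply the plausibility rules, in order.

    1. discard events fewer than ``blink_margin`` samples from a blink;
    2. merge events whose gap is below ``min_isi_s``;
    3. discard events shorter than ``min_duration_s``;
    4. discard events with peak velocity above ``max_peak_velocity``.

    ``g`` is the trace on which amplitudes and peak velocities are
    (re)measured — the denoised series for the proposed detector, the raw
    series for baselines.  Idempotent.
    """
    if any(events[k].onset_idx > events[k + 1].onset_idx for k in range(len(events) - 1)):
        raise ValueError("events must be sorted by onset")
    fs = g.sampling_rate
    if speed is None:
        speed = combined_speed(g.channels, fs)

    kept = events
    if g.blink_mask is not None and g.blink_mask.any():
        blink_idx = np.flatnonzero(g.blink_mask)
        kept = []
        for ev in events:
            # distance from the half-open event interval to the nearest blink
            d = np.minimum(np.abs(blink_idx - ev.onset_idx),
                           np.abs(blink_idx - (ev.offset_idx - 1)))
            inside = (blink_idx >= ev.onset_idx) & (blink_idx < ev.offset_idx)
            if inside.any() or d.min() < blink_margin:
                continue
            kept.append(ev)

    merged: list[SaccadeEvent] = []
    for ev in kept:
        if merged and (ev.onset_idx - merged[-1].offset_idx) / fs < min_isi_s:
            prev = merged[-1]
            merged[-1] = SaccadeEvent(
                onset_idx=prev.onset_idx, offset_idx=ev.offset_idx,
                onset_s=prev.onset_s, offset_s=ev.offset_s,
                amplitude=0.0,
                peak_velocity=max(prev.peak_velocity, ev.peak_velocity),
                duration=(ev.offset_idx - prev.onset_idx) / fs,
                truncated=ev.truncated)
        else:
            merged.append(ev)

    final = []
    for ev in merged:
        if ev.duration < min_duration_s:
            continue
        ev = _remeasure(ev, g, speed)
        if ev.peak_velocity > max_peak_velocity:
            continue
        final.append(ev)
    return final


def _interpolate_blinks(g: GazeTimeSeries) -> GazeTimeSeries:
    """Linearly interpolate masked samples so the solver sees finite data."""
    if g.blink_mask is None or not g.blink_mask.any():
        return g
    valid = ~g.blink_mask
    if not valid.any():
        raise ValueError("every sample is masked")
    idx = np.arange(len(g))

    def fill(ch: np.ndarray) -> np.ndarray:
        return np.interp(idx, idx[valid], ch[valid])

    return GazeTimeSeries(t=g.t, x=fill(g.x), sampling_rate=g.sampling_rate,
                          y=None if g.y is None else fill(g.y),
                          blink_mask=g.blink_mask, meta=dict(g.meta))


def detect_saccades(
    g: GazeTimeSeries,
    cfg=None,
    return_info: bool = False,
    **threshold_overrides,
):
    """Full proposed pipeline: denoise, differentiate, threshold, post-process.

    When ``cfg`` is ``None`` the denoiser weights are set automatically
    from the data.  Deterministic given (g, cfg).  With
    ``return_info=True`` also returns a dict holding the denoised trace
    and the parameters used (including the automatic estimates).
    """
    from .autoparams import auto_config
    from .denoise import mm_solve

    g_in = _interpolate_blinks(g)
    info: dict = {}
    if cfg is None:
        cfg, stats = auto_config(g_in)
        info["stats"] = stats
    info["config"] = cfg

    denoised_channels = []
    for ch in g_in.channels:
        res = mm_solve(ch, cfg)
        denoised_channels.append(res.x_hat)
        info.setdefault("denoise_results", []).append(res)
    g_hat = GazeTimeSeries(
        t=g.t, x=denoised_channels[0], sampling_rate=g.sampling_rate,
        y=denoised_channels[1] if len(denoised_channels) == 2 else None,
        blink_mask=g.blink_mask, meta=dict(g.meta))
    info["denoised"] = g_hat

    onset_thr = threshold_overrides.pop("onset_threshold", ONSET_THRESHOLD)
    offset_thr = threshold_overrides.pop("offset_threshold", OFFSET_THRESHOLD)
    speed = combined_speed(g_hat.channels, g.sampling_rate)
    events = threshold_events(speed, g.sampling_rate, onset_thr, offset_thr)
    events = postprocess(events, g_hat, speed=speed, **threshold_overrides)
    return (events, info) if return_info else events
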