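"""Automatic setting of the denoiser weights alpha and beta.

The regularization weights are tied to three quantities estimated from the
recording itself: the measurement-noise level sigma (deg), the average
candidate-saccade amplitude A (deg), and the average candidate-saccade
duration D (s).  With the sampling rate f (Hz):

    f <= 500:  alpha = 0.016 f sigma          beta = 0.008 f  sqrt(A) e^{5D} sigma
    f  > 500:  alpha = (0.0032 f + 6.4) sigma beta = (0.0016 f + 3.2) sqrt(A) e^{5D} sigma

The two branches coincide at f = 500 Hz, where alpha = 8 sigma and
beta = 4 sqrt(A) e^{5D} sigma.  Candidate saccades are found on a 10 Hz
low-pass velocity estimate (threshold 10 deg/s, minimum duration 12 ms,
bursts closer than 20 samples merged); sigma is the standard deviation of
the remaining fixation data after removing each fixation segment's mean.
The estimates need not be precise — the detector is insensitive to small
changes in them — which is what makes fully automatic operation viable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import GazeTimeSeries

__all__ = ["SignalStats", "lowpass_velocity", "estimate_stats", "set_alpha_beta",
           "auto_config"]

# Fallbacks when a record contains no candidate saccade: a typical normal
# saccade (8 deg, 50 ms).
FALLBACK_AMPLITUDE = 8.0
FALLBACK_DURATION = 0.05

CANDIDATE_SPEED_THRESHOLD = 10.0   # deg/s
CANDIDATE_MIN_DURATION = 0.012     # s
CANDIDATE_MERGE_GAP = 20           # samples
MIN_FIXATION_SEGMENT = 0.05        # s; shorter segments excluded from sigma


@dataclass(frozen=True)
class SignalStats:
    """Noise and saccade statistics estimated from one recording.

    ``a_hat``/``d_hat`` are ``None`` when no candidate saccade was found;
    consumers then fall back to typical normal-saccade values.
    """

    sigma_hat: float
    a_hat: float | None
    d_hat: float | None
    n_candidates: int

    def __post_init__(self) -> None:
        if self.sigma_hat < 0:
            raise ValueError("sigma_hat must be non-negative")
        if self.n_candidates > 0 and (self.a_hat is None or self.d_hat is None
                                      or self.a_hat <= 0 or self.d_hat <= 0):
            raise ValueError("a_hat and d_hat must be positive when candidates exist")


def _lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass of one channel."""
    b, a = signal.butter(4, cutoff, fs=fs)
    return signal.filtfilt(b, a, x)


def _central_diff(x: np.ndarray, fs: float) -> np.ndarray:
    v = np.empty_like(x)
    v[1:-1] = 0.5 * (x[2:] - x[:-2]) * fs
    v[0] = (x[1] - x[0]) * fs
    v[-1] = (x[-1] - x[-2]) * fs
    return v


def lowpass_velocity(g: GazeTimeSeries, cutoff: float = 10.0) -> np.ndarray:
    """Low-pass differentiated eye speed, deg/s.

    Each position channel is zero-phase low-pass filtered at ``cutoff``
    then differentiated by central differences; channels are combined as
    the Euclidean norm (absolute value for one channel).  The response
    approximates an ideal differentiator below ``cutoff`` and strongly
    attenuates higher frequencies; zero phase means saccade centers are
    not shifted in time.
    """
    fs = g.sampling_rate
    if cutoff <= 0 or cutoff >= fs / 2:
        raise ValueError("cutoff must lie strictly between 0 and the Nyquist rate")
    vs = [_central_diff(_lowpass(ch, fs, cutoff), fs) for ch in g.channels]
    if len(vs) == 1:
        return np.abs(vs[0])
    return np.hypot(vs[0], vs[1])


def _candidate_runs(speed: np.ndarray, fs: float) -> list[tuple[int, int]]:
    """Half-open index runs classified as candidate saccades."""
    above = speed > CANDIDATE_SPEED_THRESHOLD
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(speed))
    runs = list(zip(starts, ends))
    # merge bursts separated by fewer than CANDIDATE_MERGE_GAP samples
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < CANDIDATE_MERGE_GAP:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    min_len = int(np.ceil(CANDIDATE_MIN_DURATION * fs))
    return [(s, e) for s, e in merged if e - s >= min_len]


def estimate_stats(g: GazeTimeSeries, cutoff: float = 10.0) -> SignalStats:
    """Estimate (sigma, A, D) from a recording.

    Requires at least one second of data.  Raises if no fixation samples
    remain after excluding candidate saccades.
    """
    fs = g.sampling_rate
    n = len(g)
    if n < fs:
        raise ValueError("need at least one second of data")
    speed = lowpass_velocity(g, cutoff)
    runs = _candidate_runs(speed, fs)

    # amplitude on the low-pass-filtered trace, duration from the run length
    if runs:
        filtered = [_lowpass(ch, fs, cutoff) for ch in g.channels]
        amps = []
        for s, e in runs:
            e_in = min(e, n - 1)
            disp = [ch[e_in] - ch[s] for ch in filtered]
            amps.append(float(np.hypot(*disp)) if len(disp) == 2 else abs(disp[0]))
        a_hat: float | None = float(np.mean(amps))
        d_hat: float | None = float(np.mean([(e - s) / fs for s, e in runs]))
    else:
        a_hat = d_hat = None

    # sigma from per-segment-centered fixation data
    in_candidate = np.zeros(n, dtype=bool)
    for s, e in runs:
        in_candidate[s:e] = True
    if g.blink_mask is not None:
        in_candidate |= g.blink_mask
    fix = ~in_candidate
    if not fix.any():
        raise ValueError("no fixation samples available for noise estimation")
    edges = np.diff(fix.astype(np.int8))
    seg_starts = list(np.flatnonzero(edges == 1) + 1)
    seg_ends = list(np.flatnonzero(edges == -1) + 1)
    if fix[0]:
        seg_starts.insert(0, 0)
    if fix[-1]:
        seg_ends.append(n)
    min_seg = int(np.ceil(MIN_FIXATION_SEGMENT * fs))
    residuals = []
    for s, e in zip(seg_starts, seg_ends):
        if e - s < min_seg:
            continue
        for ch in g.channels:
            seg = ch[s:e]
            residuals.append(seg - seg.mean())
    if not residuals:
        raise ValueError("no fixation segment long enough for noise estimation")
    sigma_hat = float(np.std(np.concatenate(residuals)))
    return SignalStats(sigma_hat=sigma_hat, a_hat=a_hat, d_hat=d_hat,
                       n_candidates=len(runs))


def set_alpha_beta(stats: SignalStats, sampling_rate: float) -> tuple[float, float]:
    """Map (sigma, A, D) estimates and the sampling rate to (alpha, beta)."""
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    f = sampling_rate
    sigma = stats.sigma_hat
    a = stats.a_hat if stats.a_hat is not None else FALLBACK_AMPLITUDE
    d = stats.d_hat if stats.d_hat is not None else FALLBACK_DURATION
    if f <= 500:
        alpha = 0.016 * f * sigma
        beta = 0.008 * f * np.sqrt(a) * np.exp(5.0 * d) * sigma
    else:
        alpha = (0.0032 * f + 6.4) * sigma
        beta = (0.0016 * f + 3.2) * np.sqrt(a) * np.exp(5.0 * d) * sigma
    return float(alpha), float(beta)


def auto_config(g: GazeTimeSeries, **denoise_kwargs):
    """Estimate stats and build a :class:`~saccadekit.denoise.DenoiseConfig`.

    Returns ``(config, stats)`` so callers can log the estimates.
    """
    from .denoise import DenoiseConfig

    stats = estimate_stats(g)
    alpha, beta = set_alpha_beta(stats, g.sampling_rate)
    return DenoiseConfig(alpha=alpha, beta=beta, **denoise_kwargs), stats
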