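"""Parametric simulation of saccadic eye-movement time-series.

A recording is modeled as a sequence of fixations (constant gaze angle)
interleaved with saccades drawn from a three-parameter waveform model.
Each saccade is parameterized by (eta, c, A): eta is the subject's maximum
attainable peak angular velocity (deg/s), c sets the proportionality
between peak velocity and amplitude for small saccades (deg), and A is the
movement amplitude (deg).  The peak velocity of a saccade follows the main
sequence Vp = eta * (1 - exp(-A / c)), so "slow" (pathological) saccades
are simulated simply by lowering eta.

Measurement noise is additive white Gaussian noise of standard deviation
sigma (deg), which is the accepted noise model for video eye trackers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GazeTimeSeries, SaccadeEvent
from .detect import ONSET_THRESHOLD, OFFSET_THRESHOLD, central_velocity, threshold_events

__all__ = [
    "SaccadeParams",
    "ScanpathSpec",
    "soft_ramp",
    "soft_ramp_deriv",
    "saccade_waveform",
    "peak_velocity_closed_form",
    "saccade_support",
    "synthesize_scanpath",
    "add_noise",
    "random_scanpath_spec",
    "NORMAL_PROFILE",
    "SLOW_PROFILE",
]

# (eta deg/s, c deg) pairs placing simulated saccades inside or below the
# normative main-sequence band.
NORMAL_PROFILE = (550.0, 6.0)
SLOW_PROFILE = (150.0, 6.0)

# Tail truncation level for the (infinitely supported) model waveform, deg.
_TAIL_TOL = 1e-4


@dataclass(frozen=True)
class SaccadeParams:
    """Main-sequence parameters of one model saccade."""

    eta: float  # maximum attainable peak velocity, deg/s
    c: float    # amplitude scale of the main sequence, deg
    A: float    # saccade amplitude, deg

    def __post_init__(self) -> None:
        for name in ("eta", "c", "A"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")


@dataclass
class ScanpathSpec:
    """Full description of one simulated recording.

    ``fixation_durations`` must contain exactly ``len(saccades) + 1``
    entries: a fixation precedes and follows every saccade.  ``signs``
    gives the direction of each saccade (+1 rightward, -1 leftward).
    """

    sampling_rate: float
    saccades: list[SaccadeParams]
    signs: list[int]
    fixation_durations: list[float]
    start_position: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.fixation_durations) != len(self.saccades) + 1:
            raise ValueError("need len(saccades) + 1 fixation durations")
        if len(self.signs) != len(self.saccades):
            raise ValueError("need one sign per saccade")
        if any(d <= 0 for d in self.fixation_durations):
            raise ValueError("fixation durations must be positive")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def soft_ramp(u):
    """Soft ramp f(u): u + 0.25 e^{-2u} for u >= 0, 0.25 e^{2u} for u <= 0.

    Smooth (C^1) transition from 0 to the identity; the building block of
    the saccade waveform.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("soft_ramp requires finite input")
    out = np.where(u >= 0, u + 0.25 * np.exp(-2.0 * np.clip(u, 0, None)),
                   0.25 * np.exp(2.0 * np.clip(u, None, 0)))
    return out if out.ndim else float(out)


def soft_ramp_deriv(u):
    """Derivative of :func:`soft_ramp`: 1 - 0.5 e^{-2u} (u>=0), 0.5 e^{2u} (u<=0)."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("soft_ramp_deriv requires finite input")
    out = np.where(u >= 0, 1.0 - 0.5 * np.exp(-2.0 * np.clip(u, 0, None)),
                   0.5 * np.exp(2.0 * np.clip(u, None, 0)))
    return out if out.ndim else float(out)


def saccade_waveform(p: SaccadeParams, t, onset: float = 0.0):
    """Position waveform of one saccade, deg.

    s(t) = c f(eta (t-onset)/c) - c f(eta (t-onset)/c - A/c); tends to 0 as
    t -> -inf and to A as t -> +inf.  ``onset`` shifts the waveform in time.
    """
    u = p.eta * (np.asarray(t, dtype=float) - onset) / p.c
    return p.c * soft_ramp(u) - p.c * soft_ramp(u - p.A / p.c)


def saccade_velocity_analytic(p: SaccadeParams, t, onset: float = 0.0):
    """Analytic time derivative of :func:`saccade_waveform`, deg/s."""
    u = p.eta * (np.asarray(t, dtype=float) - onset) / p.c
    return p.eta * (soft_ramp_deriv(u) - soft_ramp_deriv(u - p.A / p.c))


def peak_velocity_closed_form(p: SaccadeParams) -> float:
    """Main-sequence peak velocity Vp = eta (1 - e^{-A/c}), deg/s."""
    return p.eta * (1.0 - np.exp(-p.A / p.c))


def saccade_support(p: SaccadeParams, tol: float = _TAIL_TOL) -> tuple[float, float]:
    """Time interval outside which |waveform - asymptote| < ``tol`` deg.

    Returned relative to ``onset=0``; the waveform midpoint (peak velocity)
    is at A / (2 eta).
    """
    # Left tail: s(t) <= 0.25 c exp(2 eta t / c); right tail symmetric past A/eta.
    half = (p.c / (2.0 * p.eta)) * np.log(0.25 * p.c / tol)
    return (-half, p.A / p.eta + half)


def synthesize_scanpath(spec: ScanpathSpec) -> tuple[GazeTimeSeries, list[SaccadeEvent]]:
    """Build the noise-free series and its ground-truth event list.

    Fixation segments are exactly constant; each saccade waveform is
    truncated where it is within 1e-4 deg of its asymptotes and linearly
    renormalized so segments join continuously and the displacement of
    saccade j is exactly ``signs[j] * A_j``.  Ground-truth onsets/offsets
    are defined by applying the same hysteresis velocity rule used by the
    detector (open above 30 deg/s, close below 10 deg/s) to the
    noise-free central-difference velocity, so that simulation truth and
    detection share one timing convention.
    """
    fs = spec.sampling_rate
    if any(d < 0.04 for d in spec.fixation_durations):
        raise ValueError(
            "fixation durations must be at least 40 ms; shorter gaps make "
            "adjacent saccades indistinguishable from one movement")
    supports = [saccade_support(p) for p in spec.saccades]
    sac_durs = [b - a for a, b in supports]
    total = sum(spec.fixation_durations) + sum(sac_durs)
    n = int(round(total * fs))
    t = np.arange(n) / fs

    x = np.empty(n)
    level = spec.start_position
    cursor = 0.0  # running segment start time
    for j, p in enumerate(spec.saccades):
        fix_end = cursor + spec.fixation_durations[j]
        seg = (t >= cursor) & (t < fix_end)
        x[seg] = level
        a, b = supports[j]
        tau = t[(t >= fix_end) & (t < fix_end + sac_durs[j])] - fix_end
        s = saccade_waveform(p, tau, onset=-a)
        s0, s1 = saccade_waveform(p, np.array([a, b]), onset=0.0)
        s = (s - s0) * (p.A / (s1 - s0))  # endpoints exactly 0 and A
        idx0 = int(np.searchsorted(t, fix_end, side="left"))
        x[idx0:idx0 + len(s)] = level + spec.signs[j] * s
        level += spec.signs[j] * p.A
        cursor = fix_end + sac_durs[j]
    x[t >= cursor] = level

    g = GazeTimeSeries(t=t, x=x, sampling_rate=fs,
                       meta={"seed": spec.seed, "noise_sigma": 0.0})

    speed = np.abs(central_velocity(x, fs))
    raw_events = threshold_events(speed, fs)
    truth: list[SaccadeEvent] = []
    for ev in raw_events:
        i, j_ = ev.onset_idx, ev.offset_idx
        amp = abs(x[min(j_, n - 1)] - x[i])
        truth.append(SaccadeEvent(
            onset_idx=i, offset_idx=j_, onset_s=i / fs, offset_s=j_ / fs,
            amplitude=amp, peak_velocity=float(speed[i:j_].max()),
            duration=(j_ - i) / fs, truncated=ev.truncated))
    if len(truth) != len(spec.saccades):
        raise ValueError(
            f"expected {len(spec.saccades)} ground-truth events, found {len(truth)}; "
            "fixations may be too short relative to saccade support")
    return g, truth


def add_noise(g: GazeTimeSeries, sigma: float, seed: int) -> GazeTimeSeries:
    """Add i.i.d. zero-mean Gaussian noise of std ``sigma`` deg to each channel."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    x = g.x + rng.normal(0.0, sigma, size=len(g)) if sigma > 0 else g.x.copy()
    y = None
    if g.y is not None:
        y = g.y + rng.normal(0.0, sigma, size=len(g)) if sigma > 0 else g.y.copy()
    meta = dict(g.meta)
    meta.update({"noise_sigma": sigma, "noise_seed": seed})
    return GazeTimeSeries(t=g.t.copy(), x=x, sampling_rate=g.sampling_rate,
                          y=y, blink_mask=None if g.blink_mask is None else g.blink_mask.copy(),
                          meta=meta)


def random_scanpath_spec(
    n_saccades: int,
    sampling_rate: float = 500.0,
    profile: str = "normal",
    seed: int = 0,
    amplitude_range: tuple[float, float] = (2.0, 20.0),
    fixation_range: tuple[float, float] = (0.3, 0.8),
    position_bound: float = 25.0,
    noise_sigma: float = 0.0,
) -> ScanpathSpec:
    """Draw a randomized recording specification.

    Amplitudes are uniform on ``amplitude_range`` deg, fixation durations
    uniform on ``fixation_range`` s, saccade directions random but flipped
    whenever the cumulative gaze angle would leave ``±position_bound`` deg
    (keeping simulated gaze within a realistic oculomotor range).
    ``profile`` selects the (eta, c) pair: "normal" or "slow".
    """
    if profile not in ("normal", "slow"):
        raise ValueError("profile must be 'normal' or 'slow'")
    eta, c = NORMAL_PROFILE if profile == "normal" else SLOW_PROFILE
    rng = np.random.default_rng(seed)
    amps = rng.uniform(*amplitude_range, size=n_saccades)
    fixes = rng.uniform(*fixation_range, size=n_saccades + 1)
    signs, pos = [], 0.0
    for a in amps:
        s = 1 if rng.random() < 0.5 else -1
        if abs(pos + s * a) > position_bound:
            s = -s
        signs.append(s)
        pos += s * a
    return ScanpathSpec(
        sampling_rate=sampling_rate,
        saccades=[SaccadeParams(eta=eta, c=c, A=float(a)) for a in amps],
        signs=signs,
        fixation_durations=[float(d) for d in fixes],
        noise_sigma=noise_sigma,
        seed=seed,
    )
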