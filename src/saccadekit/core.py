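"""Core containers shared across the pipeline.

Units are fixed package-wide: time in seconds, gaze angle in degrees,
velocity in degrees/second, sampling rate in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GazeTimeSeries", "SaccadeEvent"]


@dataclass
class GazeTimeSeries:
    """A uniformly sampled eye-position recording.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing with spacing
        ``1/sampling_rate`` (within numeric tolerance).
    x : ndarray
        Horizontal gaze angle in degrees.
    sampling_rate : float
        Sampling rate in Hz.
    y : ndarray, optional
        Vertical gaze angle in degrees.
    blink_mask : ndarray of bool, optional
        True where the sample is invalid (blink / track loss).  ``None``
        means every sample is valid.
    meta : dict
        Free-form provenance (e.g. the simulation seed).
    """

    t: np.ndarray
    x: np.ndarray
    sampling_rate: float
    y: np.ndarray | None = None
    blink_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != self.x.shape:
                raise ValueError("x and y must have the same length")
        if self.blink_mask is not None:
            self.blink_mask = np.asarray(self.blink_mask, dtype=bool)
            if self.blink_mask.shape != self.x.shape:
                raise ValueError("blink_mask must match the signal length")
        if self.t.shape != self.x.shape:
            raise ValueError("t and x must have the same length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            expected = 1.0 / self.sampling_rate
            if np.max(np.abs(dt - expected)) > 1e-6 * expected + 1e-12:
                raise ValueError("t must be uniformly spaced at 1/sampling_rate")
        valid = ~self.blink_mask if self.blink_mask is not None else slice(None)
        if not np.all(np.isfinite(self.x[valid])):
            raise ValueError("x contains non-finite values at valid samples")
        if self.y is not None and not np.all(np.isfinite(self.y[valid])):
            raise ValueError("y contains non-finite values at valid samples")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def channels(self) -> list[np.ndarray]:
        """Position channels as a list ([x] or [x, y])."""
        return [self.x] if self.y is None else [self.x, self.y]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.x) / self.sampling_rate


@dataclass
class SaccadeEvent:
    """One saccade, detected or ground truth.

    The sample interval is 0-based and half-open: ``[onset_idx, offset_idx)``.
    ``duration = (offset_idx - onset_idx) / sampling_rate``.
    """

    onset_idx: int
    offset_idx: int
    onset_s: float
    offset_s: float
    amplitude: float
    peak_velocity: float
    duration: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.offset_idx <= self.onset_idx:
            raise ValueError("offset_idx must exceed onset_idx")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.peak_velocity <= 0:
            raise ValueError("peak_velocity must be positive")

    def overlap(self, other: "SaccadeEvent") -> float:
        """Temporal overlap with another event, in seconds (0 if disjoint)."""
        return max(0.0, min(self.offset_s, other.offset_s) - max(self.onset_s, other.onset_s))
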