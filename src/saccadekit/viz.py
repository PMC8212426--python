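"""Static figure export: raw and denoised traces with shaded detections."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import GazeTimeSeries, SaccadeEvent
from .detect import combined_speed

__all__ = ["plot_detection"]


def plot_detection(g: GazeTimeSeries, denoised: GazeTimeSeries,
                   events: list[SaccadeEvent], path) -> None:
    """Two-panel figure: position (raw + denoised) and denoised speed."""
    fig, (ax0, ax1) = plt.subplots(2, 1, sharex=True, figsize=(10, 6))
    ax0.plot(g.t, g.x, color="0.7", lw=0.8, label="raw")
    ax0.plot(denoised.t, denoised.x, color="k", lw=1.2, label="denoised")
    if g.y is not None:
        ax0.plot(g.t, g.y, color="0.85", lw=0.8)
        ax0.plot(denoised.t, denoised.y, color="0.4", lw=1.2)
    ax0.set_ylabel("gaze angle (deg)")
    ax0.legend(loc="upper right", frameon=False)
    speed = combined_speed(denoised.channels, denoised.sampling_rate)
    ax1.plot(denoised.t, speed, color="k", lw=1.0)
    ax1.axhline(30, color="0.5", ls="--", lw=0.8)
    ax1.axhline(10, color="0.5", ls=":", lw=0.8)
    ax1.set_ylabel("speed (deg/s)")
    ax1.set_xlabel("time (s)")
    for ax in (ax0, ax1):
        for e in events:
            ax.axvspan(e.onset_s, e.offset_s, color="0.8", alpha=0.5, zorder=0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
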