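"""Figure helpers: fatigue traces and input-space activation projections."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless safe; callers save to file
import matplotlib.pyplot as plt

from .assessment import MFTrace
from .introspect import Projection

__all__ = ["plot_trace", "plot_projection"]


def plot_trace(
    trace: MFTrace,
    train_head_end: Optional[float] = None,
    train_tail_start: Optional[float] = None,
    path: str | Path | None = None,
    title: str = "Mental fatigue assessment",
):
    """Smoothed fatigue level over time.

    Green dashed line: end of the low-fatigue training region; red dashed
    line: start of the high-fatigue training region.
    """
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trace.times, trace.levels, lw=1.5, color="C0")
    if train_head_end is not None:
        ax.axvline(train_head_end, color="green", ls="--", lw=1,
                   label="end of low-MF training data")
    if train_tail_start is not None:
        ax.axvline(train_tail_start, color="red", ls="--", lw=1,
                   label="start of high-MF training data")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("MF level")
    ax.set_ylim(-0.05, 1.05)
    ax.set_title(title)
    ax.legend(loc="center left", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)
    return fig


def plot_projection(
    projection: Projection,
    channel_names: Sequence[str],
    rate: float = 128.0,
    path: str | Path | None = None,
):
    """Multi-panel view of one kernel's input-space projection, per channel."""
    vals = projection.values
    n = vals.shape[0]
    t = [i / rate for i in range(vals.shape[1])]
    fig, axes = plt.subplots(n, 1, figsize=(8, 1.2 * n), sharex=True)
    if n == 1:
        axes = [axes]
    for ax, row, name in zip(axes, vals, channel_names):
        ax.plot(t, row, lw=0.7)
        ax.set_ylabel(name, rotation=0, ha="right", fontsize=8)
    axes[-1].set_xlabel("time (s)")
    fig.suptitle(
        f"Layer {projection.source_layer}, kernel {projection.source_kernel} "
        f"projection (|a| = {projection.activation_norm:.3g})"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)
    return fig
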