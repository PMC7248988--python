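"""Streaming mental-fatigue trace: classify every 4 s, smooth over 5 steps.

The assessment loop replays a recording as a stream: every 4 s the most
recent 6 s fused window is classified, and the fatigue level emitted at that
step is the mean of the high-class indicator over the trailing 5 steps
(fewer during warm-up).  The smoothing is what surfaces *transition states*:
on data between the two trained boundary classes the classifier flips
inconsistently, and the trailing mean converts that inconsistency into
intermediate levels — while bounding any one-step change to 1/5 once the
window is full.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .fusion import CaseConfig, FusedSegment, Normalizer, WindowSpec, segment

__all__ = ["AssessmentStep", "MFTrace", "assess_stream", "smooth_levels"]


@dataclass
class AssessmentStep:
    """One 4 s loop iteration: the raw classifier output for the latest window."""

    time: float  # seconds; end of the 6 s window
    raw_output: np.ndarray  # class probability vector
    raw_class: int  # argmax (ties -> lower index)


@dataclass
class MFTrace:
    """Time-indexed smoothed fatigue level, one entry per completed step."""

    times: np.ndarray
    levels: np.ndarray
    steps: List[AssessmentStep] = field(default_factory=list)
    window_steps: int = 5

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.levels = np.asarray(self.levels, dtype=np.float64)
        if self.times.shape != self.levels.shape:
            raise ValueError("times and levels must have equal length")
        if self.levels.size and (self.levels.min() < 0 or self.levels.max() > 1):
            raise ValueError("trace levels must lie in [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.column_stack([self.times, self.levels])


def smooth_levels(values: Sequence[float], window_steps: int = 5) -> np.ndarray:
    """Trailing moving average over at most ``window_steps`` entries.

    During warm-up (fewer than ``window_steps`` completed steps) the mean runs
    over the steps available so far.
    """
    v = np.asarray(values, dtype=np.float64)
    out = np.empty_like(v)
    for i in range(v.size):
        lo = max(0, i - window_steps + 1)
        out[i] = v[lo:i + 1].mean()
    return out


def assess_stream(
    model,
    recording,
    case: CaseConfig | None = None,
    normalizer: Normalizer | None = None,
    window: WindowSpec | None = None,
    window_steps: int = 5,
    smooth: str = "class",
) -> MFTrace:
    """Produce the smoothed fatigue trace for a full recording.

    Steps occur at t = 6, 10, 14, ... s; each classifies the half-open 6 s
    window ending at t.  ``smooth="class"`` (default) averages the predicted
    class indicator, reproducing stepped-then-smoothed traces;
    ``smooth="probs"`` averages the high-class probability instead.
    Deterministic given model and recording, and identical to batch
    segmentation + per-segment prediction + trailing moving average.
    """
    if smooth not in ("class", "probs"):
        raise ValueError("smooth must be 'class' or 'probs'")
    case = case or CaseConfig(3)
    window = window or WindowSpec(rate=recording.rate)
    if recording.duration < window.length_s:
        raise ValueError("too short: recording shorter than one window")

    segments = segment(recording, window, case)
    if normalizer is not None:
        segments = normalizer.apply_all(segments)

    x = np.stack([s.matrix for s in segments])
    probs = model.predict_proba(x)
    if probs.shape[0] != len(segments):
        raise ValueError("model returned wrong number of predictions")

    steps = []
    raw_values = []
    for seg_obj, p in zip(segments, probs):
        cls = int(np.argmax(p))
        steps.append(
            AssessmentStep(
                time=seg_obj.start_time + window.length_s,
                raw_output=np.asarray(p, dtype=np.float64),
                raw_class=cls,
            )
        )
        raw_values.append(float(cls) if smooth == "class" else float(p[1]))

    levels = smooth_levels(raw_values, window_steps)
    times = np.array([s.time for s in steps])
    return MFTrace(times=times, levels=levels, steps=steps, window_steps=window_steps)
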