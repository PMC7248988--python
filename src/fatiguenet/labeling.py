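"""KSS-derived mental-fatigue scale and boundary-region label assignment.

Participants report Karolinska Sleepiness Scale scores (1 = very alert ...
9 = very sleepy) before and after a session.  The lower report anchors the
low-fatigue boundary class (numeric level 0.0), the higher report the
high-fatigue boundary (1.0); any KSS values strictly between become
transition states, spaced evenly in (0, 1).  Only the first and last 20% of
the session's segments receive training labels (low / high); the middle
stays unknown and is used to probe generalization and the transition phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .fusion import FusedSegment

__all__ = [
    "KSSReport",
    "MFScale",
    "LabelAssignment",
    "derive_scale",
    "assign_labels",
    "labeled_subset",
    "LABEL_LOW",
    "LABEL_HIGH",
    "LABEL_UNKNOWN",
]

LABEL_LOW = "low"
LABEL_HIGH = "high"
LABEL_UNKNOWN = "unknown"


@dataclass(frozen=True)
class KSSReport:
    """Pre/post self-reported sleepiness for one subject, both in 1-9."""

    subject_id: str
    kss_pre: int
    kss_post: int

    def __post_init__(self) -> None:
        for name, v in (("kss_pre", self.kss_pre), ("kss_post", self.kss_post)):
            if int(v) != v or not 1 <= int(v) <= 9:
                raise ValueError(f"{name} must be an integer in [1, 9], got {v!r}")


@dataclass(frozen=True)
class MFScale:
    """Per-subject fatigue scale derived from the KSS range.

    ``numeric_map`` sends the low boundary KSS level to 0.0, the high boundary
    to 1.0 and each intermediate KSS level to an evenly spaced value between.
    """

    low_level: int
    high_level: int
    transition_levels: Tuple[int, ...]
    numeric_map: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.low_level < self.high_level:
            raise ValueError("low_level must be strictly below high_level")
        expected = tuple(range(self.low_level + 1, self.high_level))
        if self.transition_levels != expected:
            raise ValueError("transition_levels must be the KSS values strictly between")


def derive_scale(report: KSSReport) -> MFScale:
    """Build the subject's fatigue scale from the pre/post KSS pair.

    Raises for equal scores: with no reported progression there are no two
    boundary classes to train on.
    """
    if report.kss_pre == report.kss_post:
        raise ValueError(
            "degenerate scale: no MF progression reported (kss_pre == kss_post)"
        )
    low = min(report.kss_pre, report.kss_post)
    high = max(report.kss_pre, report.kss_post)
    span = high - low
    numeric = {k: (k - low) / span for k in range(low, high + 1)}
    return MFScale(
        low_level=low,
        high_level=high,
        transition_levels=tuple(range(low + 1, high)),
        numeric_map=numeric,
    )


@dataclass
class LabelAssignment:
    """Per-segment training labels: low in the head, high in the tail."""

    labels: List[str]
    head_frac: float
    tail_frac: float

    @property
    def n_low(self) -> int:
        return self.labels.count(LABEL_LOW)

    @property
    def n_high(self) -> int:
        return self.labels.count(LABEL_HIGH)

    @property
    def n_unknown(self) -> int:
        return self.labels.count(LABEL_UNKNOWN)


def assign_labels(
    segments: Sequence[FusedSegment],
    scale: MFScale | None = None,
    head_frac: float = 0.2,
    tail_frac: float = 0.2,
) -> LabelAssignment:
    """Label the first ``floor(head_frac * N)`` segments low and the last
    ``floor(tail_frac * N)`` high; everything else unknown.

    Floor rounding is deliberate: boundary labels never bleed toward the
    middle of the session.  Segment ``label`` attributes are set in place.
    """
    if len(segments) == 0:
        raise ValueError("segment list is empty")
    if head_frac + tail_frac >= 1.0:
        raise ValueError("head_frac + tail_frac must be < 1")
    starts = [s.start_time for s in segments]
    if any(t2 <= t1 for t1, t2 in zip(starts, starts[1:])):
        raise ValueError("segments must be in strictly increasing time order")

    n = len(segments)
    n_low = int(np.floor(head_frac * n))
    n_high = int(np.floor(tail_frac * n))
    if n_low == 0 or n_high == 0:
        raise ValueError("insufficient segments to label")

    labels = [LABEL_UNKNOWN] * n
    for i in range(n_low):
        labels[i] = LABEL_LOW
    for i in range(n - n_high, n):
        labels[i] = LABEL_HIGH
    for s, lab in zip(segments, labels):
        s.label = None if lab == LABEL_UNKNOWN else lab
    return LabelAssignment(labels=labels, head_frac=head_frac, tail_frac=tail_frac)


def labeled_subset(segments: Sequence[FusedSegment]) -> List[FusedSegment]:
    """The segments carrying a boundary label, in time order."""
    return [s for s in segments if s.label in (LABEL_LOW, LABEL_HIGH)]
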