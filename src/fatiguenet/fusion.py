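"""Raw-level sensor fusion: common clock, normalization, sliding-window stacking.

Disparate channels (microvolts, degrees Celsius, millimetres, m/s^2) are
brought to a common 128 Hz clock, z-normalized with *training-set* statistics,
cut by a 6 s window sliding in 4 s steps (2 s overlap), and stacked into a
channels-by-768 matrix — the 2D input the convolutional classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .signals import CHANNEL_LAYOUT, EEG_CHANNEL_NAMES, Recording

__all__ = [
    "WindowSpec",
    "FusedSegment",
    "CaseConfig",
    "CASE_CHANNELS",
    "resample",
    "segment",
    "segment_count",
    "Normalizer",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 6 s windows, 2 s overlap, 128 Hz."""

    length_s: float = 6.0
    overlap_s: float = 2.0
    rate: float = 128.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_s < self.length_s:
            raise ValueError("require 0 <= overlap_s < length_s")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def step_s(self) -> float:
        return self.length_s - self.overlap_s

    @property
    def samples_per_segment(self) -> int:
        return int(round(self.length_s * self.rate))

    @property
    def step_samples(self) -> int:
        return int(round(self.step_s * self.rate))

    @property
    def overlap_samples(self) -> int:
        return int(round(self.overlap_s * self.rate))


@dataclass
class FusedSegment:
    """One channels x samples window; the classifier's 2D input."""

    matrix: np.ndarray
    start_time: float
    channel_order: List[str]
    label: Optional[str] = None  # "low" | "high" | None (unknown)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("segment matrix must be 2-D (channels x samples)")
        if self.matrix.shape[0] != len(self.channel_order):
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but channel_order lists "
                f"{len(self.channel_order)} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


#: Sensor-configuration channel subsets.  Case 4 is the union of 1-3.
CASE_CHANNELS: Dict[int, Tuple[str, ...]] = {
    1: ("ecg", "emg", "temperature"),
    2: ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z",
        "pupil_left", "pupil_right"),
    3: EEG_CHANNEL_NAMES,
    4: tuple(name for name, _, _ in CHANNEL_LAYOUT),
}


@dataclass(frozen=True)
class CaseConfig:
    """Sensor subset selector: 1 = ECG/EMG/temp, 2 = eye tracker, 3 = EEG, 4 = all."""

    case_id: int = 3

    def __post_init__(self) -> None:
        if self.case_id not in CASE_CHANNELS:
            raise ValueError(f"case_id must be in {sorted(CASE_CHANNELS)}")

    @property
    def channel_names(self) -> Tuple[str, ...]:
        return CASE_CHANNELS[self.case_id]

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


def resample(recording: Recording, target_rate: float) -> Recording:
    """Linearly interpolate every channel onto the target clock.

    Duration is preserved within one sample period.  No anti-alias filter is
    applied; synthetic content is band-limited below Nyquist by construction
    (a documented limitation for real downsampled data).
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if recording.n_samples < 2:
        raise ValueError("need at least 2 samples per channel to resample")
    if target_rate == recording.rate:
        return recording
    t_old = recording.times()
    n_new = int(round(recording.duration * target_rate))
    t_new = np.arange(n_new) / target_rate
    data = np.vstack([np.interp(t_new, t_old, row) for row in recording.samples])
    return Recording(
        channels=[
            type(c)(name=c.name, modality=c.modality, native_rate=c.native_rate,
                    units=c.units)
            for c in recording.channels
        ],
        samples=data,
        rate=target_rate,
        duration=recording.duration,
        session_meta=dict(recording.session_meta),
    )


def segment_count(duration: float, window: WindowSpec) -> int:
    """floor((duration - length) / step) + 1; trailing partial windows dropped."""
    if duration < window.length_s:
        raise ValueError("too short: recording shorter than one window")
    return int(np.floor((duration - window.length_s) / window.step_s)) + 1


def segment(
    recording: Recording,
    window: WindowSpec | None = None,
    case: CaseConfig | None = None,
) -> List[FusedSegment]:
    """Cut the recording into fused segments for one sensor configuration.

    Windows are half-open ``[k * step, k * step + length)`` starting at t = 0;
    consecutive segments share exactly ``overlap_s * rate`` columns.  Rows
    follow the fixed documented channel order of the case.
    """
    window = window or WindowSpec(rate=recording.rate)
    case = case or CaseConfig(4)
    if recording.rate != window.rate:
        raise ValueError(
            f"recording rate {recording.rate} Hz differs from window rate "
            f"{window.rate} Hz; resample first"
        )
    names = recording.channel_names
    rows = []
    for ch in case.channel_names:
        if ch not in names:
            raise ValueError(f"recording is missing requested channel {ch!r}")
        rows.append(names.index(ch))
    data = recording.samples[rows]

    n_seg = segment_count(recording.duration, window)
    L, step = window.samples_per_segment, window.step_samples
    out: List[FusedSegment] = []
    for k in range(n_seg):
        s = k * step
        out.append(
            FusedSegment(
                matrix=data[:, s:s + L].copy(),
                start_time=s / window.rate,
                channel_order=list(case.channel_names),
            )
        )
    return out


@dataclass
class Normalizer:
    """Per-channel z-normalization with training-set statistics.

    Statistics are pooled over all training segments and time points; the
    standard deviation is floored at 1e-8 so constant channels map to zero.
    Fit on training data only — applying the same statistics to validation or
    streaming data avoids leakage.
    """

    mean_: np.ndarray = field(default_factory=lambda: np.empty(0))
    sd_: np.ndarray = field(default_factory=lambda: np.empty(0))
    channel_order: List[str] = field(default_factory=list)

    SD_FLOOR = 1e-8

    @staticmethod
    def fit(training_segments: Sequence[FusedSegment]) -> "Normalizer":
        if len(training_segments) == 0:
            raise ValueError("cannot fit normalizer on an empty training set")
        order = training_segments[0].channel_order
        stacked = np.concatenate([s.matrix for s in training_segments], axis=1)
        mean = stacked.mean(axis=1)
        sd = np.maximum(stacked.std(axis=1), Normalizer.SD_FLOOR)
        return Normalizer(mean_=mean, sd_=sd, channel_order=list(order))

    def apply(self, seg: FusedSegment) -> FusedSegment:
        if seg.channel_order != self.channel_order:
            raise ValueError("segment channel order does not match normalizer")
        return FusedSegment(
            matrix=(seg.matrix - self.mean_[:, None]) / self.sd_[:, None],
            start_time=seg.start_time,
            channel_order=list(seg.channel_order),
            label=seg.label,
        )

    def apply_all(self, segments: Sequence[FusedSegment]) -> List[FusedSegment]:
        return [self.apply(s) for s in segments]
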