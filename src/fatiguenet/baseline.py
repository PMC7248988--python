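"""Band-power threshold baseline — the separability certificate.

A deliberately simple classifier independent of the CNN path: average the
alpha-band (8-13 Hz) Welch power over the EEG channels of each segment,
learn the midpoint between class means on the training set, and threshold.
When the synthetic generator plants an alpha-amplitude contrast, this
baseline must score perfectly; it certifies that any CNN shortfall is a
modelling problem rather than inseparable data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .fusion import FusedSegment
from .labeling import LABEL_HIGH, LABEL_LOW
from .signals import BAND_EDGES, EEG_CHANNEL_NAMES, band_power

__all__ = ["BandPowerClassifier", "segment_band_power"]


def segment_band_power(
    seg: FusedSegment, rate: float = 128.0, band: Tuple[float, float] | None = None
) -> float:
    """Mean band power over the segment's EEG channels (all rows if no EEG)."""
    band = band or BAND_EDGES["alpha"]
    rows = [i for i, n in enumerate(seg.channel_order) if n in EEG_CHANNEL_NAMES]
    if not rows:
        rows = list(range(seg.n_channels))
    return float(np.mean([band_power(seg.matrix[i], rate, band) for i in rows]))


@dataclass
class BandPowerClassifier:
    """Midpoint threshold on mean EEG alpha power; high power => high fatigue."""

    threshold: float = 0.0
    high_is_above: bool = True
    rate: float = 128.0
    band: Tuple[float, float] = BAND_EDGES["alpha"]

    def fit(self, segments: Sequence[FusedSegment]) -> "BandPowerClassifier":
        lows = [segment_band_power(s, self.rate, self.band)
                for s in segments if s.label == LABEL_LOW]
        highs = [segment_band_power(s, self.rate, self.band)
                 for s in segments if s.label == LABEL_HIGH]
        if not lows or not highs:
            raise ValueError("need labeled segments from both classes")
        self.threshold = (float(np.mean(lows)) + float(np.mean(highs))) / 2.0
        self.high_is_above = float(np.mean(highs)) >= float(np.mean(lows))
        return self

    def predict(self, segments: Sequence[FusedSegment]) -> np.ndarray:
        p = np.array([segment_band_power(s, self.rate, self.band) for s in segments])
        above = p > self.threshold
        return (above if self.high_is_above else ~above).astype(np.int64)

    def accuracy(self, segments: Sequence[FusedSegment]) -> float:
        y = np.array([1 if s.label == LABEL_HIGH else 0 for s in segments])
        return float(np.mean(self.predict(segments) == y))
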