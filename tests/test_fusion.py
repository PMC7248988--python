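"""Resampling, windowing arithmetic, channel-case algebra and normalization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatiguenet.fusion import (
    CaseConfig,
    FusedSegment,
    Normalizer,
    WindowSpec,
    resample,
    segment,
    segment_count,
)
from fatiguenet.signals import (
    ChannelSpec,
    FatigueProfile,
    GeneratorConfig,
    Recording,
    simulate_session,
)


def toy_recording(duration=30.0, rate=128.0, n_channels=1, fill=None):
    n = int(round(rate * duration))
    if fill is None:
        data = np.arange(n_channels * n, dtype=np.float64).reshape(n_channels, n)
    else:
        data = np.full((n_channels, n), fill, dtype=np.float64)
    chans = [ChannelSpec(name=f"c{i}", modality="ecg", native_rate=rate)
             for i in range(n_channels)]
    # reuse 'ecg' modality: windowing logic is modality-agnostic
    return Recording(channels=chans, samples=data, rate=rate, duration=duration)


class TestResample:
    def test_same_rate_is_identity(self):
        rec = toy_recording()
        assert resample(rec, 128.0) is rec

    def test_constant_channel_stays_constant(self):
        rec = toy_recording(duration=10.0, rate=37.0, fill=3.25)
        out = resample(rec, 128.0)
        assert out.rate == 128.0
        assert np.allclose(out.samples, 3.25)

    def test_sinusoid_upsampling_tracks_analytic_signal(self):
        rate0, dur, f = 64.0, 8.0, 4.0
        t0 = np.arange(int(rate0 * dur)) / rate0
        rec = Recording(
            channels=[ChannelSpec("c0", "ecg", rate0)],
            samples=np.sin(2 * np.pi * f * t0)[None, :],
            rate=rate0, duration=dur,
        )
        out = resample(rec, 128.0)
        t1 = out.times()
        inside = t1 <= t0[-1]  # the final half-sample-period is held constant
        err = np.abs(out.samples[0, inside] - np.sin(2 * np.pi * f * t1[inside]))
        assert err.max() < 0.05  # linear-interp error bound for f/fs = 1/16

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            resample(toy_recording(), 0.0)


class TestSegmentation:
    @pytest.mark.parametrize("duration,expected_n,expected_starts", [
        (22.0, 5, [0.0, 4.0, 8.0, 12.0, 16.0]),
        (6.0, 1, [0.0]),
        (9.9, 1, [0.0]),
        (10.0, 2, [0.0, 4.0]),
    ])
    def test_count_and_starts(self, duration, expected_n, expected_starts):
        rec = toy_recording(duration=duration)
        segs = segment(rec, WindowSpec(), case=_single_channel_case())
        assert len(segs) == expected_n
        assert [s.start_time for s in segs] == expected_starts
        assert all(s.n_samples == 768 for s in segs)

    def test_sixty_second_case3_geometry(self):
        rec = simulate_session(GeneratorConfig(seed=0), FatigueProfile.ramp(60.0), 60.0)
        segs = segment(rec, WindowSpec(), CaseConfig(3))
        assert len(segs) == 14  # floor((60 - 6) / 4) + 1
        assert all(s.matrix.shape == (6, 768) for s in segs)
        assert segs[0].channel_order == list(CaseConfig(3).channel_names)

    def test_overlap_columns_match_source(self):
        rec = toy_recording(duration=22.0)
        segs = segment(rec, WindowSpec(), _single_channel_case())
        for a, b in zip(segs, segs[1:]):
            assert np.array_equal(a.matrix[:, -256:], b.matrix[:, :256])
            src_start = int(round(b.start_time * rec.rate))
            assert np.array_equal(
                b.matrix[:, :256], rec.samples[:, src_start:src_start + 256]
            )

    def test_case_row_algebra_and_count_invariance(self):
        rec = simulate_session(GeneratorConfig(seed=0), FatigueProfile.ramp(60.0), 60.0)
        rows = {c: segment(rec, WindowSpec(), CaseConfig(c))[0].n_channels
                for c in (1, 2, 3, 4)}
        assert rows[4] == rows[1] + rows[2] + rows[3] == 17
        counts = {c: len(segment(rec, WindowSpec(), CaseConfig(c)))
                  for c in (1, 2, 3, 4)}
        assert len(set(counts.values())) == 1

    def test_missing_channel_named_in_error(self):
        rec = toy_recording()
        with pytest.raises(ValueError, match="AF3"):
            segment(rec, WindowSpec(), CaseConfig(3))

    def test_too_short_recording_rejected(self):
        rec = toy_recording(duration=4.0)
        with pytest.raises(ValueError, match="too short"):
            segment(rec, WindowSpec(), _single_channel_case())

    @given(duration=st.integers(min_value=6, max_value=600))
    @settings(max_examples=60, deadline=None)
    def test_count_formula(self, duration):
        assert segment_count(float(duration), WindowSpec()) == \
            int(np.floor((duration - 6) / 4)) + 1


def _single_channel_case():
    """A case selecting the toy recording's single channel."""

    class _Case:
        channel_names = ("c0",)
        n_channels = 1
        case_id = 0

    return _Case()


def _make_segments(rng, n=6, channels=2, length=64):
    return [
        FusedSegment(matrix=rng.normal(size=(channels, length)),
                     start_time=4.0 * i, channel_order=["a", "b"][:channels])
        for i in range(n)
    ]


class TestNormalizer:
    def test_self_fit_is_zero_mean_unit_sd(self, rng):
        segs = _make_segments(rng)
        norm = Normalizer.fit(segs)
        pooled = np.concatenate([norm.apply(s).matrix for s in segs], axis=1)
        assert np.abs(pooled.mean(axis=1)).max() < 1e-9
        assert np.abs(pooled.std(axis=1) - 1).max() < 1e-6

    def test_constant_channel_maps_to_zero(self):
        segs = [FusedSegment(matrix=np.full((1, 32), 7.0), start_time=0.0,
                             channel_order=["a"])]
        norm = Normalizer.fit(segs)
        assert np.allclose(norm.apply(segs[0]).matrix, 0.0)

    def test_shift_moves_values_by_c_over_sd(self, rng):
        segs = _make_segments(rng)
        norm = Normalizer.fit(segs)
        c = 2.5
        shifted = FusedSegment(matrix=segs[0].matrix + c, start_time=0.0,
                               channel_order=segs[0].channel_order)
        delta = norm.apply(shifted).matrix - norm.apply(segs[0]).matrix
        assert np.allclose(delta, c / norm.sd_[:, None])

    def test_refit_on_scaled_data_gives_identical_segments(self, rng):
        """Scale invariance of the fused pipeline: z-scoring absorbs any
        positive per-recording gain once the normalizer is refitted."""
        segs = _make_segments(rng)
        scaled = [FusedSegment(matrix=10.0 * s.matrix, start_time=s.start_time,
                               channel_order=s.channel_order) for s in segs]
        a = Normalizer.fit(segs).apply_all(segs)
        b = Normalizer.fit(scaled).apply_all(scaled)
        for x, y in zip(a, b):
            assert np.allclose(x.matrix, y.matrix)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Normalizer.fit([])

    def test_channel_order_mismatch_rejected(self, rng):
        segs = _make_segments(rng)
        norm = Normalizer.fit(segs)
        other = FusedSegment(matrix=segs[0].matrix, start_time=0.0,
                             channel_order=["b", "a"])
        with pytest.raises(ValueError, match="channel order"):
            norm.apply(other)
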