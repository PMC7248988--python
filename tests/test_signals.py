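"""Generator and spectral-utility behaviour: determinism, effect injection,
band-power estimation against independent spectral references."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sp_signal
from scipy import stats

from fatiguenet.fusion import CASE_CHANNELS
from fatiguenet.signals import (
    BAND_EDGES,
    EEG_CHANNEL_NAMES,
    ChannelSpec,
    FatigueProfile,
    GeneratorConfig,
    band_power,
    simulate_session,
)

RATE = 128.0


def periodogram_band_power(x, rate, band):
    """Independent reference: raw periodogram integrated over the band."""
    f, p = sp_signal.periodogram(x, fs=rate)
    m = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[m], f[m]))


class TestSessionGeneration:
    def test_channel_suite_and_sample_count(self):
        rec = simulate_session(GeneratorConfig(seed=0), FatigueProfile.ramp(60.0), 60.0)
        assert rec.samples.shape == (17, 7680)  # 60 s x 128 Hz
        names = set(rec.channel_names)
        assert set(EEG_CHANNEL_NAMES) <= names
        # sensor cases partition the suite: 3 + 8 + 6 = 17
        assert (len(CASE_CHANNELS[1]) + len(CASE_CHANNELS[2])
                + len(CASE_CHANNELS[3])) == len(CASE_CHANNELS[4]) == 17
        assert set(CASE_CHANNELS[1]) | set(CASE_CHANNELS[2]) | set(CASE_CHANNELS[3]) \
            == set(CASE_CHANNELS[4]) == names

    def test_bit_identical_under_same_seed(self):
        cfg = GeneratorConfig(seed=42)
        prof = FatigueProfile.ramp(30.0)
        a = simulate_session(cfg, prof, 30.0)
        b = simulate_session(cfg, prof, 30.0)
        assert np.array_equal(a.samples, b.samples)
        c = simulate_session(GeneratorConfig(seed=43), prof, 30.0)
        assert not np.array_equal(a.samples, c.samples)

    def test_zero_effect_size_is_spectrally_flat_in_time(self):
        """With identical low/high endpoints the latent level must leave no
        spectral footprint: first vs last third alpha power indistinguishable."""
        diffs = []
        for seed in range(10):
            cfg = GeneratorConfig(
                seed=seed,
                eeg_band_amplitudes_high=dict(GeneratorConfig().eeg_band_amplitudes_low),
                heart_rate_high=75.0, emg_amplitude_high=1.0,
            )
            rec = simulate_session(cfg, FatigueProfile.ramp(90.0), 90.0)
            third = rec.n_samples // 3
            for name in EEG_CHANNEL_NAMES:
                x = rec.channel(name)
                diffs.append(
                    band_power(x[-third:], RATE, BAND_EDGES["alpha"])
                    - band_power(x[:third], RATE, BAND_EDGES["alpha"])
                )
        _, p = stats.ttest_1samp(diffs, 0.0)
        assert p > 0.01  # two-sided test fails to reject at alpha = 0.01

    def test_alpha_doubling_raises_second_half_power_every_channel(self):
        cfg = GeneratorConfig(seed=5)  # default high alpha = 2 x low
        dur = 120.0
        prof = FatigueProfile(((0.0, 0.0), (59.99, 0.0), (60.01, 1.0), (dur, 1.0)))
        rec = simulate_session(cfg, prof, dur)
        half = rec.n_samples // 2
        for name in EEG_CHANNEL_NAMES:
            x = rec.channel(name)
            lo = band_power(x[:half], RATE, BAND_EDGES["alpha"])
            hi = band_power(x[half:], RATE, BAND_EDGES["alpha"])
            assert hi > lo
            # independent periodogram oracle agrees on the ordering
            assert periodogram_band_power(x[half:], RATE, BAND_EDGES["alpha"]) > \
                periodogram_band_power(x[:half], RATE, BAND_EDGES["alpha"])

    def test_monotone_alpha_across_staircase_majority_of_seeds(self):
        """3-step latent staircase => nondecreasing mean alpha power, majority
        vote over 20 seeds."""
        dur = 60.0
        prof = FatigueProfile(
            ((0.0, 0.0), (19.99, 0.0), (20.0, 0.5), (39.99, 0.5), (40.0, 1.0), (dur, 1.0))
        )
        wins = 0
        for seed in range(20):
            rec = simulate_session(GeneratorConfig(seed=seed), prof, dur)
            third = rec.n_samples // 3
            powers = []
            for k in range(3):
                seg = slice(k * third, (k + 1) * third)
                powers.append(np.mean([
                    band_power(rec.channel(n)[seg], RATE, BAND_EDGES["alpha"])
                    for n in EEG_CHANNEL_NAMES
                ]))
            if powers[0] <= powers[1] <= powers[2]:
                wins += 1
        assert wins > 10

    def test_too_short_session_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            simulate_session(GeneratorConfig(), FatigueProfile.ramp(4.0), 4.0)

    def test_profile_duration_must_match(self):
        with pytest.raises(ValueError, match="invalid fatigue profile"):
            simulate_session(GeneratorConfig(), FatigueProfile.ramp(30.0), 60.0)


class TestFatigueProfile:
    @pytest.mark.parametrize("breakpoints", [
        ((0.0, 0.0),),                          # single point
        ((0.0, 0.0), (10.0, 1.5)),              # level out of range
        ((5.0, 0.0), (10.0, 1.0)),              # does not start at 0
        ((0.0, 0.0), (10.0, 0.5), (10.0, 1.0)),  # non-increasing times
    ])
    def test_malformed_profiles_rejected(self, breakpoints):
        with pytest.raises(ValueError, match="invalid fatigue profile"):
            FatigueProfile(breakpoints)

    def test_piecewise_linear_interpolation(self):
        prof = FatigueProfile(((0.0, 0.0), (10.0, 1.0), (20.0, 1.0)))
        assert prof.level(5.0) == pytest.approx(0.5)
        assert prof.level(15.0) == pytest.approx(1.0)


class TestBandPower:
    def test_sinusoid_concentrates_in_its_band(self, rng):
        t = np.arange(int(8 * RATE)) / RATE
        x = np.sin(2 * np.pi * 10.0 * t)
        alpha = band_power(x, RATE, BAND_EDGES["alpha"])
        beta = band_power(x, RATE, BAND_EDGES["beta"])
        assert alpha > 10 * beta

    def test_zero_signal_has_zero_power(self):
        assert band_power(np.zeros(1024), RATE, BAND_EDGES["alpha"]) == pytest.approx(0.0)

    def test_white_noise_power_scales_with_bandwidth(self, rng):
        x = rng.standard_normal(2 ** 15)
        alpha = band_power(x, RATE, BAND_EDGES["alpha"])
        beta = band_power(x, RATE, BAND_EDGES["beta"])
        expected = (30.0 - 13.0) / (13.0 - 8.0)  # flat-spectrum bandwidth ratio
        assert beta / alpha == pytest.approx(expected, rel=0.30)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band out of range"):
            band_power(np.ones(1024), RATE, (60.0, 70.0))

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            band_power(np.ones(100), RATE, BAND_EDGES["alpha"])


class TestValidation:
    def test_eeg_channel_names_restricted(self):
        with pytest.raises(ValueError, match="EEG channel name"):
            ChannelSpec(name="Cz", modality="eeg", native_rate=128.0)

    def test_unknown_modality_rejected(self):
        with pytest.raises(ValueError, match="unknown modality"):
            ChannelSpec(name="x", modality="optical", native_rate=10.0)

    def test_band_keys_must_be_canonical(self):
        with pytest.raises(ValueError, match="band keys"):
            GeneratorConfig(eeg_band_amplitudes_low={"delta": 1.0})

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            GeneratorConfig(noise_sd={"ecg": -1.0, "emg": 0.1, "temperature": 0.1,
                                      "eeg": 1.0, "eye": 0.1})
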