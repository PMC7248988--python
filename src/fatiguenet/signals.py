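"""Physiological recording types and a synthetic multimodal session generator.

The sensor suite emulated here mirrors a wearable monitoring rig for operators
of demanding tasks: a 3-lead ECG (one signal channel), a 3-lead EMG (one
channel), an axillary temperature probe, a 6-channel EEG headset (AF3, F3, O1,
O2, F4, AF4) and an eye tracker exposing a 3-DOF accelerometer, a 3-DOF
gyroscope and left/right pupil diameters — 17 channels in total, all resampled
onto a common 128 Hz clock.

Fatigue enters through a latent trajectory ``lambda(t)`` in [0, 1].  Each
modality's generating parameters are the convex combination
``(1 - lambda) * low + lambda * high`` of configured endpoints:

* EEG band amplitudes rise in the theta and alpha bands as fatigue builds
  (the canonical spectral signature of mental fatigue);
* heart rate drifts down;
* EMG amplitude (muscle-contraction intensity) declines;
* axillary temperature follows a slow circadian-like drift;
* pupil diameter shifts by a configurable (default neutral) delta.

Every draw comes from a single seeded generator, so a config + seed pair
reproduces a session bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "BAND_EDGES",
    "EEG_CHANNEL_NAMES",
    "CHANNEL_LAYOUT",
    "ChannelSpec",
    "Recording",
    "FatigueProfile",
    "GeneratorConfig",
    "simulate_session",
    "band_power",
]

#: Canonical EEG frequency bands (Hz): delta, theta, alpha, beta.
BAND_EDGES: Dict[str, Tuple[float, float]] = {
    "delta": (0.3, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

EEG_CHANNEL_NAMES = ("AF3", "F3", "O1", "O2", "F4", "AF4")

VALID_MODALITIES = ("ecg", "emg", "temperature", "eeg", "eye")

#: Fixed channel order of a full synthetic session: ECG/EMG/temperature block,
#: eye-tracker block, EEG block.  Fusion relies on this order being stable.
CHANNEL_LAYOUT: Tuple[Tuple[str, str, str], ...] = (
    ("ecg", "ecg", "mV"),
    ("emg", "emg", "a.u."),
    ("temperature", "temperature", "degC"),
    ("acc_x", "eye", "m/s^2"),
    ("acc_y", "eye", "m/s^2"),
    ("acc_z", "eye", "m/s^2"),
    ("gyro_x", "eye", "deg/s"),
    ("gyro_y", "eye", "deg/s"),
    ("gyro_z", "eye", "deg/s"),
    ("pupil_left", "eye", "mm"),
    ("pupil_right", "eye", "mm"),
    ("AF3", "eeg", "uV"),
    ("F3", "eeg", "uV"),
    ("O1", "eeg", "uV"),
    ("O2", "eeg", "uV"),
    ("F4", "eeg", "uV"),
    ("AF4", "eeg", "uV"),
)

_SINES_PER_BAND = 8  # random-phase sinusoid mixture components per EEG band


@dataclass(frozen=True)
class ChannelSpec:
    """Metadata for one physiological channel."""

    name: str
    modality: str
    native_rate: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.modality not in VALID_MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r} for channel {self.name!r}; "
                f"expected one of {VALID_MODALITIES}"
            )
        if not self.native_rate > 0:
            raise ValueError(f"native_rate must be > 0 for channel {self.name!r}")
        if self.modality == "eeg" and self.name not in EEG_CHANNEL_NAMES:
            raise ValueError(
                f"EEG channel name {self.name!r} not in {EEG_CHANNEL_NAMES}"
            )


@dataclass
class Recording:
    """Multichannel time series on a common clock.

    ``samples`` is a (n_channels, n_samples) float array; row order matches
    ``channels``.  ``session_meta`` carries subject id and pre/post KSS scores.
    """

    channels: List[ChannelSpec]
    samples: np.ndarray
    rate: float
    duration: float
    session_meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not self.rate > 0:
            raise ValueError("rate must be > 0")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique within a recording")
        expected = int(round(self.rate * self.duration))
        if self.samples.shape != (len(self.channels), expected):
            raise ValueError(
                f"samples shape {self.samples.shape} does not match "
                f"({len(self.channels)}, {expected}) from rate x duration"
            )
        for key in ("kss_pre", "kss_post"):
            v = self.session_meta.get(key)
            if v is not None and (int(v) != v or not 1 <= int(v) <= 9):
                raise ValueError(f"{key} must be an integer in [1, 9], got {v!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def channel_names(self) -> List[str]:
        return [c.name for c in self.channels]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"recording has no channel named {name!r}") from None
        return self.samples[idx]

    def times(self) -> np.ndarray:
        """Sample times in seconds; index 0 is t = 0."""
        return np.arange(self.n_samples) / self.rate


@dataclass(frozen=True)
class FatigueProfile:
    """Piecewise-linear latent fatigue trajectory lambda(t) in [0, 1].

    Breakpoints are (time s, level) pairs with strictly increasing times;
    the first time must be 0 and the last must equal the session duration.
    """

    breakpoints: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        bp = tuple((float(t), float(v)) for t, v in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        if len(bp) < 2:
            raise ValueError("invalid fatigue profile: need at least 2 breakpoints")
        times = [t for t, _ in bp]
        levels = [v for _, v in bp]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("invalid fatigue profile: times must strictly increase")
        if times[0] != 0.0:
            raise ValueError("invalid fatigue profile: first breakpoint must be t = 0")
        if any(not 0.0 <= v <= 1.0 for v in levels):
            raise ValueError("invalid fatigue profile: levels must lie in [0, 1]")

    @property
    def duration(self) -> float:
        return self.breakpoints[-1][0]

    def level(self, t: np.ndarray | float) -> np.ndarray:
        times = np.array([p[0] for p in self.breakpoints])
        levels = np.array([p[1] for p in self.breakpoints])
        return np.interp(np.asarray(t, dtype=np.float64), times, levels)

    @staticmethod
    def constant(level: float, duration: float) -> "FatigueProfile":
        return FatigueProfile(((0.0, level), (duration, level)))

    @staticmethod
    def ramp(duration: float, start: float = 0.0, end: float = 1.0) -> "FatigueProfile":
        return FatigueProfile(((0.0, start), (duration, end)))

    @staticmethod
    def step(duration: float, at: float, low: float = 0.0, high: float = 1.0,
             transition: float = 1.0) -> "FatigueProfile":
        """Step from `low` to `high` at time `at` over a short `transition`."""
        if not 0 < at < at + transition < duration:
            raise ValueError("invalid fatigue profile: step outside session")
        return FatigueProfile(
            ((0.0, low), (at, low), (at + transition, high), (duration, high))
        )


def _default_low_bands() -> Dict[str, float]:
    return {"delta": 20.0, "theta": 10.0, "alpha": 10.0, "beta": 5.0}


def _default_high_bands() -> Dict[str, float]:
    # Theta and alpha amplitudes rise with fatigue; alpha doubles (2:1).
    return {"delta": 20.0, "theta": 15.0, "alpha": 20.0, "beta": 5.0}


def _default_noise() -> Dict[str, float]:
    return {"ecg": 0.05, "emg": 0.05, "temperature": 0.02, "eeg": 5.0, "eye": 0.05}


@dataclass
class GeneratorConfig:
    """Endpoint parameters of the synthetic session generator.

    Amplitudes are interpreted so that an EEG band with envelope amplitude A
    contributes variance A^2 / 2 (the mixture of 8 random-phase unit sinusoids
    is scaled by 1/sqrt(8)).  ``temp_drift`` is degrees C per hour.  Pupil and
    eye-motion channels default to fatigue-neutral behaviour.
    """

    eeg_band_amplitudes_low: Dict[str, float] = field(default_factory=_default_low_bands)
    eeg_band_amplitudes_high: Dict[str, float] = field(default_factory=_default_high_bands)
    heart_rate_low: float = 75.0
    heart_rate_high: float = 62.0
    emg_amplitude_low: float = 1.0
    emg_amplitude_high: float = 0.4
    temp_start: float = 36.8
    temp_drift: float = -0.05
    pupil_mean: float = 4.0
    pupil_fatigue_delta: float = 0.0
    noise_sd: Dict[str, float] = field(default_factory=_default_noise)
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.eeg_band_amplitudes_low, self.eeg_band_amplitudes_high):
            if set(d) != set(BAND_EDGES):
                raise ValueError(
                    f"EEG band keys must be exactly {sorted(BAND_EDGES)}, got {sorted(d)}"
                )
            if any(v < 0 for v in d.values()):
                raise ValueError("EEG band amplitudes must be nonnegative")
        for name in ("heart_rate_low", "heart_rate_high",
                     "emg_amplitude_low", "emg_amplitude_high", "pupil_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise sds must be nonnegative")

    def to_dict(self) -> Dict[str, object]:
        return {
            "eeg_band_amplitudes_low": dict(self.eeg_band_amplitudes_low),
            "eeg_band_amplitudes_high": dict(self.eeg_band_amplitudes_high),
            "heart_rate_low": self.heart_rate_low,
            "heart_rate_high": self.heart_rate_high,
            "emg_amplitude_low": self.emg_amplitude_low,
            "emg_amplitude_high": self.emg_amplitude_high,
            "temp_start": self.temp_start,
            "temp_drift": self.temp_drift,
            "pupil_mean": self.pupil_mean,
            "pupil_fatigue_delta": self.pupil_fatigue_delta,
            "noise_sd": dict(self.noise_sd),
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: Dict[str, object]) -> "GeneratorConfig":
        return GeneratorConfig(**d)  # type: ignore[arg-type]

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


def simulate_session(
    config: GeneratorConfig,
    profile: FatigueProfile,
    duration: float = 600.0,
    rate: float = 128.0,
    session_meta: Dict[str, object] | None = None,
) -> Recording:
    """Generate one synthetic multimodal session.

    At latent level lambda(t) every modality parameter is the convex
    combination ``(1 - lambda) * low + lambda * high`` of the config
    endpoints.  Fully reproducible from ``config.seed``.
    """
    if duration < 6.0:
        raise ValueError("session too short to segment (duration < 6 s)")
    max_edge = max(hi for _, hi in BAND_EDGES.values())
    if rate <= 2 * max_edge:
        raise ValueError(f"rate must exceed {2 * max_edge} Hz to carry all EEG bands")
    if abs(profile.duration - duration) > 1e-9:
        raise ValueError(
            "invalid fatigue profile: last breakpoint time must equal session duration"
        )

    n = int(round(rate * duration))
    t = np.arange(n) / rate
    lam = profile.level(t)
    rng = np.random.default_rng(config.seed)

    def mix(low: float, high: float) -> np.ndarray:
        return (1.0 - lam) * low + lam * high

    rows: List[np.ndarray] = []

    # --- ECG: Gaussian pulse train at the instantaneous heart rate ---
    hr = mix(config.heart_rate_low, config.heart_rate_high)  # beats/min
    phase = np.cumsum(hr / 60.0) / rate  # beats elapsed
    frac = phase - np.round(phase)  # distance to nearest beat, in beat units
    ecg = np.exp(-0.5 * (frac / 0.04) ** 2)
    ecg += rng.normal(0.0, config.noise_sd["ecg"], n)
    rows.append(ecg)

    # --- EMG: amplitude-modulated broadband noise ---
    env = mix(config.emg_amplitude_low, config.emg_amplitude_high)
    emg = env * rng.standard_normal(n)
    emg += rng.normal(0.0, config.noise_sd["emg"], n)
    rows.append(emg)

    # --- temperature: slow drift plus noise ---
    temp = config.temp_start + config.temp_drift * (t / 3600.0)
    temp = temp + rng.normal(0.0, config.noise_sd["temperature"], n)
    rows.append(temp)

    # --- eye tracker: fatigue-neutral motion channels ---
    eye_sd = config.noise_sd["eye"]
    for mean in (0.0, 0.0, 9.81):  # accelerometer, gravity on z
        rows.append(mean + eye_sd * rng.standard_normal(n))
    for _ in range(3):  # gyroscope, deg/s around zero
        rows.append(10.0 * eye_sd * rng.standard_normal(n))
    pupil = mix(config.pupil_mean, config.pupil_mean + config.pupil_fatigue_delta)
    for _ in range(2):
        rows.append(pupil + eye_sd * rng.standard_normal(n))

    # --- EEG: per-band random-phase sinusoid mixtures, fatigue-modulated ---
    for _name in EEG_CHANNEL_NAMES:
        chan = np.zeros(n)
        for band, (lo, hi) in BAND_EDGES.items():
            freqs = rng.uniform(lo, hi, _SINES_PER_BAND)
            phases = rng.uniform(0.0, 2.0 * np.pi, _SINES_PER_BAND)
            base = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
            base = base.sum(axis=0) / np.sqrt(_SINES_PER_BAND)
            amp = mix(
                config.eeg_band_amplitudes_low[band],
                config.eeg_band_amplitudes_high[band],
            )
            chan += amp * base
        chan += rng.normal(0.0, config.noise_sd["eeg"], n)
        rows.append(chan)

    specs = [
        ChannelSpec(name=name, modality=mod, native_rate=rate, units=units)
        for name, mod, units in CHANNEL_LAYOUT
    ]
    return Recording(
        channels=specs,
        samples=np.vstack(rows),
        rate=rate,
        duration=duration,
        session_meta=dict(session_meta or {}),
    )


def band_power(
    samples: Sequence[float] | np.ndarray,
    rate: float,
    band: Tuple[float, float],
) -> float:
    """Integrated Welch power-spectral-density over a frequency band.

    Uses 2 s Hann segments (50% overlap), giving 0.5 Hz resolution at 128 Hz.
    Returns the PSD integral over [band[0], band[1]] — nonnegative, in units
    of signal variance.
    """
    x = np.asarray(samples, dtype=np.float64)
    lo, hi = band
    if not 0.0 < lo < hi < rate / 2.0:
        raise ValueError(f"band out of range: ({lo}, {hi}) vs Nyquist {rate / 2}")
    if x.size < 2 * rate:
        raise ValueError("sequence too short: need at least 2 s of samples")
    nperseg = int(2 * rate)
    freqs, psd = sp_signal.welch(x, fs=rate, nperseg=nperseg)
    mask = (freqs >= lo) & (freqs <= hi)
    return float(np.trapezoid(psd[mask], freqs[mask]))
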