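"""Demo-scale study conditions shared by the examples, tests and CLI defaults.

One "study" here is a pair of 60-minute synthetic sessions from the same subject
whose latent fatigue steps from 0 to 1 mid-session, recorded with the full
17-channel suite, assessed with the EEG-only sensor configuration (the best
performing one) and a reduced-filter model that trains in minutes on one CPU.
The generator defaults plant a 2:1 alpha-amplitude contrast between the high
and low fatigue states with 5 uV broadband EEG noise.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .cnn import ModelSpec, TrainConfig
from .fusion import CaseConfig, FusedSegment, Normalizer, WindowSpec, segment
from .labeling import KSSReport, assign_labels, derive_scale, labeled_subset
from .signals import FatigueProfile, GeneratorConfig, Recording, simulate_session

__all__ = [
    "DEMO_DURATION",
    "demo_generator_config",
    "demo_profile",
    "demo_sessions",
    "demo_labeled_segments",
    "demo_model_spec",
    "demo_train_config",
]

DEMO_DURATION = 3600.0  # seconds per session (the shortest real session length)


def demo_generator_config(seed: int = 0) -> GeneratorConfig:
    return GeneratorConfig(seed=int(seed))


def demo_profile(duration: float = DEMO_DURATION) -> FatigueProfile:
    """Latent fatigue stepping from 0 to 1 at mid-session.

    The transition takes 30 s (or a tenth of a short session), so the head
    and tail fifths used for training are pure boundary states.
    """
    transition = min(30.0, duration / 10.0)
    return FatigueProfile.step(duration, at=(duration - transition) / 2.0,
                               transition=transition)


def demo_sessions(seed: int = 0, duration: float = DEMO_DURATION,
                  n_sessions: int = 2) -> List[Recording]:
    """Seeded session pair (same subject, KSS 2 -> 4, independent noise)."""
    ss = np.random.SeedSequence(int(seed))
    seeds = [int(s % (2**31)) for s in ss.generate_state(n_sessions)]
    profile = demo_profile(duration)
    meta = {"subject_id": "demo", "kss_pre": 2, "kss_post": 4}
    return [
        simulate_session(demo_generator_config(s), profile, duration,
                         session_meta=dict(meta))
        for s in seeds
    ]


def demo_labeled_segments(
    seed: int = 0,
    duration: float = DEMO_DURATION,
    case: CaseConfig | None = None,
    n_sessions: int = 2,
) -> Tuple[List[FusedSegment], Normalizer, List[Recording]]:
    """Segment, label (first/last 20%), normalize on the labeled training pool.

    Returns (normalized labeled segments, the fitted normalizer, the raw
    sessions) — everything needed to train and then stream-assess.
    """
    case = case or CaseConfig(3)
    window = WindowSpec()
    sessions = demo_sessions(seed, duration, n_sessions)
    scale = derive_scale(KSSReport("demo", 2, 4))
    labeled: List[FusedSegment] = []
    for rec in sessions:
        segs = segment(rec, window, case)
        assign_labels(segs, scale)
        labeled.extend(labeled_subset(segs))
    normalizer = Normalizer.fit(labeled)
    return normalizer.apply_all(labeled), normalizer, sessions


def demo_model_spec(case: CaseConfig | None = None) -> ModelSpec:
    case = case or CaseConfig(3)
    return ModelSpec.demo(case.n_channels)


def demo_train_config(seed: int = 0, folds: int = 5) -> TrainConfig:
    return TrainConfig(folds=folds, seed=int(seed))
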