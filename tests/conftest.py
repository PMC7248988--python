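"""Shared fixtures.

The expensive artifacts — the 30-minute synthetic session pair and the
cross-validated classifier — are built once per test session and shared by
the training, streaming-assessment and introspection tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from fatiguenet.cnn import train_cv, train_final
from fatiguenet.demo import (
    demo_labeled_segments,
    demo_model_spec,
    demo_train_config,
)

STUDY_SEED = 101


@pytest.fixture(scope="session")
def demo_data():
    """(normalized labeled segments, normalizer, raw sessions) at demo scale."""
    return demo_labeled_segments(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def cv_report(demo_data):
    segs, _, _ = demo_data
    return train_cv(segs, demo_model_spec(), demo_train_config(seed=STUDY_SEED, folds=5))


@pytest.fixture(scope="session")
def trained_model(demo_data):
    """A deployable classifier trained on the demo study."""
    segs, normalizer, _ = demo_data
    model, _ = train_final(segs, demo_model_spec(),
                           demo_train_config(seed=STUDY_SEED, folds=5))
    return model, normalizer


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
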