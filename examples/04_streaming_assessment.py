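"""Streaming fatigue trace: train once, then replay a fresh session.

Every 4 s the latest 6 s fused window is classified and the trailing-5-step
mean of the class indicator becomes the fatigue level — the smoothing that
turns inconsistent boundary-class decisions into visible transition states.
"""

import numpy as np

from fatiguenet import CaseConfig, assess_stream, train_final, simulate_session
from fatiguenet.demo import (
    demo_generator_config,
    demo_labeled_segments,
    demo_model_spec,
    demo_profile,
    demo_train_config,
)

segs, normalizer, _ = demo_labeled_segments(seed=7, duration=1800.0)
model, _ = train_final(segs, demo_model_spec(), demo_train_config(seed=7, folds=1))

fresh = simulate_session(demo_generator_config(seed=99), demo_profile(1800.0), 1800.0)
trace = assess_stream(model, fresh, CaseConfig(3), normalizer)

print(f"{trace.times.size} assessment steps at t = 6, 10, ... "
      f"{trace.times[-1]:.0f} s")
print(f"initial level {trace.levels[0]:.2f} -> final level {trace.levels[-1]:.2f}")
print(f"largest one-step change after warm-up: "
      f"{np.abs(np.diff(trace.levels[4:])).max():.2f} (bounded by 1/5)")

quarters = np.array_split(trace.levels, 4)
print("mean level per quarter of the session:",
      [f"{q.mean():.2f}" for q in quarters])
print("\nThe latent fatigue steps 0 -> 1 at mid-session; the trace crosses "
      "through intermediate values over at most 5 steps.")
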