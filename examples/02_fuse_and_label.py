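"""Fuse a session into CNN inputs and label them from KSS reports.

Shows the sliding-window arithmetic (6 s windows, 2 s overlap), the
per-subject fatigue scale derived from pre/post sleepiness scores, and the
first/last-20% training-label rule.
"""

from fatiguenet import (
    CaseConfig,
    FatigueProfile,
    GeneratorConfig,
    KSSReport,
    WindowSpec,
    assign_labels,
    derive_scale,
    segment,
    simulate_session,
)

rec = simulate_session(GeneratorConfig(seed=7), FatigueProfile.ramp(300.0), 300.0)
segs = segment(rec, WindowSpec(), CaseConfig(3))
print(f"{rec.duration:.0f} s session -> {len(segs)} segments of shape "
      f"{segs[0].matrix.shape} (floor((300-6)/4)+1 = 74)")

scale = derive_scale(KSSReport("subject-11", kss_pre=2, kss_post=4))
print(f"KSS 2 -> 4: low boundary = KSS {scale.low_level}, "
      f"high boundary = KSS {scale.high_level}, "
      f"transition states at KSS {scale.transition_levels} "
      f"(numeric {[scale.numeric_map[k] for k in scale.transition_levels]})")

labels = assign_labels(segs, scale)
print(f"labels: {labels.n_low} low / {labels.n_unknown} unknown / "
      f"{labels.n_high} high")
print("\nOnly the head and tail fifths of the session carry training labels; "
      "the middle stays unknown and is used to study generalization.")
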