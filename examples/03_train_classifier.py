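"""Cross-validated training of the fatigue CNN on a reduced synthetic study.

Uses two 30-minute sessions and 2 Monte-Carlo folds so the run finishes in
about a minute on one CPU; the shipped acceptance script runs the full
60-minute, 5-fold study.  The band-power threshold baseline certifies that
the planted alpha contrast makes the classes separable.
"""

from fatiguenet import BandPowerClassifier, train_cv
from fatiguenet.demo import demo_labeled_segments, demo_model_spec, demo_train_config

segs, normalizer, _ = demo_labeled_segments(seed=7, duration=1800.0)
print(f"labeled segments: {len(segs)} "
      f"({sum(s.label == 'low' for s in segs)} low, "
      f"{sum(s.label == 'high' for s in segs)} high)")

baseline = BandPowerClassifier().fit(segs)
print(f"band-power baseline accuracy: {baseline.accuracy(segs):.2f} "
      "(separability certificate)")

report = train_cv(segs, demo_model_spec(), demo_train_config(seed=7, folds=2))
print(f"CNN test accuracy (avg over {len(report.folds)} folds): "
      f"{report.summary()}")
for fr in report.folds:
    print(f"  fold {fr.fold}: test acc {fr.test_accuracy:.3f}, "
          f"best epoch {fr.best_epoch}, {len(fr.val_history)} epochs, "
          f"{fr.n_lr_decays} lr decays")
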