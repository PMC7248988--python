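# Methods

## Overview

`fatiguenet` implements a raw-level sensor-fusion pipeline for assessing
mental fatigue (MF) from multichannel physiological recordings. The pipeline
has five stages:

1. **Fusion** — all channels are brought to a common 128 Hz clock, z-scored
   with training-set statistics, and cut by a 6 s sliding window with 2 s
   overlap (4 s step) into channels × 768 matrices.
2. **Labeling** — a per-subject MF scale is derived from pre/post Karolinska
   Sleepiness Scale (KSS) reports; the first and last 20% of a session's
   segments receive the low/high boundary labels, the middle stays unknown.
3. **Classification** — a five-block temporal CNN maps each fused segment to
   low/high class probabilities.
4. **Streaming assessment** — every 4 s the latest window is classified and
   the trailing 5-step mean of the class indicator is emitted as the MF
   level, surfacing transition states between the trained boundaries.
5. **Introspection** — deconvolution projects any kernel's activation back
   to input coordinates to show which channels and frequencies drive it.

Because no public recordings exist for this sensor suite, a synthetic
session generator is a first-class part of the package: it defines the study
conditions under which every downstream claim is tested.

## Synthetic session generator

A session is 17 channels on a 128 Hz clock: ECG, EMG and axillary
temperature (one channel each — the 3-lead ECG/EMG rigs produce a single
signal), an eye-tracker block (3-axis accelerometer, 3-axis gyroscope,
left/right pupil diameter), and six EEG channels (AF3, F3, O1, O2, F4, AF4).
A piecewise-linear latent trajectory λ(t) ∈ [0, 1] drives fatigue; every
modality parameter is the convex combination (1 − λ)·low + λ·high of
configured endpoints.

Per modality:

- **EEG** — per-band mixtures of 8 random-phase sinusoids with frequencies
  drawn uniformly inside the canonical bands (delta 0.3–4, theta 4–8, alpha
  8–13, beta 13–30 Hz), scaled so envelope amplitude A yields band variance
  A²/2, plus white Gaussian noise. Defaults (µV): delta 20→20, theta 10→15,
  alpha 10→20, beta 5→5, noise sd 5. Rising theta/alpha with fatigue is the
  standard spectral signature; the 2:1 alpha ratio with 5 µV noise keeps the
  contrast large but not degenerate (alpha component RMS 7–14 µV).
- **ECG** — a Gaussian pulse train at the instantaneous heart rate
  (75 → 62 bpm), σ ≈ 4% of the beat period. Morphological realism (P/QRS/T
  shape) is deliberately out of scope; the classifier contract only needs a
  rate-modulated quasi-periodic signal.
- **EMG** — amplitude-modulated broadband noise (envelope 1.0 → 0.4 a.u.),
  reflecting declining muscle-contraction intensity.
- **Temperature** — 36.8 °C with a slow drift (−0.05 °C/h) plus noise; the
  drift is circadian-like and not λ-coupled.
- **Eye tracker** — fatigue-neutral by default: the literature gives no
  agreed effect direction for pupil diameter or head-motion channels, so
  `pupil_fatigue_delta` defaults to 0 and is exposed as a parameter rather
  than asserted.

All draws come from one seeded generator in a fixed order, so a
(config, seed) pair reproduces a session bit for bit.

What the generator does **not** emulate: EEG artifacts (ocular, muscular,
line noise), non-stationary spectra beyond the λ-modulation, inter-channel
correlation structure, realistic ECG/EMG morphology, or label noise in the
KSS reports. Passing tests therefore demonstrate that the pipeline recovers
a planted, artifact-free spectral contrast — not that it reaches any
particular accuracy on real recordings.

## Sensor cases

Case 1 = {ECG, EMG, temperature} (3 channels); Case 2 = eye tracker
(8 channels); Case 3 = EEG (6 channels); Case 4 = all 17. Case 3 is the
package default — the single-sensor configuration with the highest
classification accuracy and the simplest rig.

## Fusion details

- Windows are half-open [k·4 s, k·4 s + 6 s); trailing partial windows are
  dropped (the CNN input width is fixed at 768 columns), giving
  floor((T − 6)/4) + 1 segments for a T-second recording.
- Channel rows follow a fixed documented order (ECG/EMG/temp, eye block,
  EEG block) recorded in every segment, so trained models are portable.
- Per-channel z-normalization uses **training-set** statistics only (sd
  floored at 1e−8 for constant channels). Raw-level fusion of µV, °C, mm
  and m/s² is numerically unusable without it.
- Resampling is linear interpolation on the original timestamps, without an
  anti-alias filter: all synthetic content is below Nyquist by construction.
  This is a documented limitation for real downsampled data.

## MF scale and labels

The lower of the two KSS reports anchors the low-MF boundary (numeric 0.0),
the higher anchors high-MF (1.0); KSS values strictly between become
transition states spaced evenly in (0, 1) — the even spacing is a package
choice, since only the existence of intermediate states is prescribed.
Equal pre/post reports raise an error: with no reported progression there
are no two classes to train. Fractional label counts use floor rounding so
boundary labels never bleed toward the session middle; an empty labeled set
raises rather than silently training on one class. The numeric codomain is
fixed to [0, 1] so traces from subjects with different KSS ranges are
comparable.

## Classifier

Five blocks of (valid temporal convolution → ReLU → average pooling k=2)
with filter counts (256, 128, 64, 32, 32) and kernel sizes (3, 5, 7, 9, 9),
then a dense layer and softmax over K = 2 classes. On a 6 × 768 input the
temporal extents evolve 768 → 766 → 383 → 379 → 189 → 183 → 91 → 83 → 41 →
33 → 16.

The convolution is written as a true (flipped-kernel) discrete convolution

    S(i, j) = Σ_m Σ_n I(m, n) · K(i − m, j − n)

evaluated in valid mode along time with channels/filters as depth — the
single most consequential interpretation in the package: the printed
formula is 2-D, but the scalar kernel sizes identify the temporal axis as
the only convolved one. The implementation (strided windows + einsum) is
tested against a literal triple-loop transcription of the formula and
against `np.convolve`, to < 1e−6 on random instances; all layer adjoints
are verified against finite differences. Softmax subtracts the max logit
before exponentiation, making it overflow-safe and shift-invariant to 1e−9
for logits up to magnitude 1000. Argmax ties resolve to the lower class
index.

The full filter bank is ~0.5 M parameters — fine for inference but slow to
train in NumPy on one CPU — so the package ships a reduced demo bank
(16, 16, 8, 8, 8) with identical depth and kernel sizes
(`ModelSpec.demo`). All structural contracts (extent arithmetic,
projection shapes) are tested on both.

## Training protocol

"Nested 20-fold cross validation with 60/20/20 splits" cannot be a disjoint
20-fold partition (20 folds × 20% test ≠ 100%); it is implemented as
Monte-Carlo cross validation: each fold draws a fresh seeded,
label-stratified random 60/20/20 train/validation/test split. Per fold:

- train at least 15 epochs (hard cap `max_epochs`, default 200);
- after 5 consecutive epochs without validation-accuracy improvement the
  learning rate is multiplied by 0.8 (a 20% reduction), repeating every
  further 5 stale epochs;
- after 15 stale epochs training terminates;
- the best-validation weights are restored before test evaluation
  (strict improvement only — on ties the **earliest** best is kept).

The report aggregates fold test accuracies as mean ± std (population std).
The optimizer, batch size and initial rate are not prescribed anywhere, so
the package defaults are its own: Adam, batch 32, lr 3e−3 (1e−3 converges
too slowly to beat the fixed 15-epoch stop window at demo scale). He
fan-in initialization, seeded per fold from a spawned seed sequence; the
whole report is bit-reproducible from `TrainConfig.seed`.

Random segment-level splits share 2 s of signal between neighbouring train
and test segments; `split_mode="block"` provides contiguous rotated blocks
for leakage-controlled evaluation. Whether the original protocol controlled
this is unknown; both modes are provided and the random mode is the
default, matching the printed split fractions.

## Streaming assessment

Steps occur at t = 6, 10, 14, … s; each classifies the 6 s window ending at
t, and the emitted level is the mean of the high-class indicator over the
last min(5, steps so far) steps (warm-up averages what exists; a
no-warm-up variant is selectable). Averaging the *indicator* rather than
the probability reproduces the stepped-then-smoothed look of boundary-class
flicker on transition data; `smooth="probs"` switches to probability
averaging. Consequences, both tested: levels always lie in [0, 1], and
once 5 steps exist no one-step change exceeds 1/5. Note a 5-step window at
a 4 s loop covers ~22 s of signal, not the 30 s sometimes quoted for this
smoothing; the 5-step reading is implemented.

## Deconvolution introspection

For a chosen layer and kernel, all other activation maps at that layer
(block outputs: post-ReLU, post-pool) are zeroed and the survivor is pushed
back block by block: average pooling is reversed by uniform redistribution
(each pooled value split equally over its 2-sample window — the adjoint of
mean pooling; the max-pooling "switches" of the classic deconvnet have no
analogue here), ReLU is re-applied, and the layer's own kernels are applied
transposed. Biases are omitted on the reverse pass (standard deconvnet
convention). The projection lands in input coordinates (channels × 768);
per-channel L2 norms are the channel-relevance measurement. The reverse
pass is positively homogeneous, so scaling a nonnegative activation scales
the projection linearly (tested). Claims about which EEG channel matters
are subject- and data-specific and are never asserted by the tests.

## Demo study conditions and problem sizes

The shipped study (`fatiguenet.demo`) is a pair of 60-minute sessions —
the shortest real session length — from one subject (KSS 2 → 4), latent
fatigue stepping 0 → 1 at mid-session over 30 s, full sensor suite,
assessed with Case 3. This yields 899 segments per session and 716 labeled
segments for training. Cross validation runs 5 folds at demo scale with the
reduced filter bank; at this size a 5-fold run takes about a minute on one
CPU. Shorter sessions were examined and rejected: at 10–30 minutes the
labeled set is small enough that the network can memorize the training
split while the planted contrast remains perfectly separable (the
band-power baseline stays at 1.00), i.e. the failure is sample size, not
signal. The examples use 30-minute sessions and 2 folds to finish faster;
their accuracy is slightly below the full study's.

The band-power threshold baseline (mean EEG alpha power, midpoint
threshold) accompanies every training run as a separability certificate:
when it scores 1.00 and the CNN does not, the shortfall is a modelling or
sample-size issue, not inseparable data.

## Numerical choices and degenerate inputs

- Welch PSD with 2 s Hann segments (0.5 Hz resolution) for band power;
  integration by the trapezoid rule over the band.
- Normalizer sd floor 1e−8; constant channels normalize to zero.
- floor rounding everywhere fractional counts appear (segments, labels,
  splits); split remainders go to the training partition.
- Recordings round-trip losslessly through CSV (17 significant digits,
  round-trip float parsing) with a JSON sidecar for channel metadata and
  KSS scores.
- Softmax outputs can underflow to exact zero for logit differences beyond
  ~745 (float64); sums and shift-invariance still hold to 1e−9.

## Known limitations

- Synthetic-only validation; no artifact handling for real EEG.
- Linear-interpolation resampling aliases real wideband content.
- The permutation-null band (accuracy ≈ 0.5) has fold-to-fold spread of a
  few points at 716 segments; it is a chance-level check, not a calibrated
  significance test.
- Single-subject analysis only; no pooled or transfer models.
- Intermediate in-session KSS reports are not consumed.
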