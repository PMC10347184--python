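# Methods

## The problem

`stresskit` models a wearable-sensing stress study: participants solve Sudoku
puzzles under three environmental scenarios (1: noisy/disturbing audio-video,
2: observed by another person, 3: comforting audio-video) at one of two
puzzle difficulties, while three wearables record photoplethysmography (PPG,
3 optical channels at 55 Hz), single-lead ECG (512 Hz) and single-channel
EEG (512 Hz) for a nominal 15 minutes per session. After each session the
participant reports stress on a 0–8 scale, mapped to three classes
(0–4 → low, 5–7 → medium, 8 → high). The task is 3-class classification of
10-second signal windows.

Because the human recordings are not publicly deposited, the package ships a
synthetic-cohort generator with the statistical structure the classifiers
are supposed to exploit, so every downstream stage is testable end to end.

## Synthetic cohort generator

**Label model.** One score per participant × scenario. Two modes:

* `paper-like` — class probabilities (0.744, 0.211, 0.044), matching the
  observed segment counts 6030/1710/360 out of 8100. Scenario and difficulty
  act as log-space tilts on the class weights (scenario 1: +0.45, scenario 3:
  −0.45, hard: +0.15, medium: −0.15), chosen so that scenario-averaged
  proportions stay at the target while reproducing the qualitative pattern:
  stress up in the noisy scenario, down under comforting stimuli, hard
  puzzles slightly more stressful. Within a class, scores follow a fixed
  mildly peaked distribution (class 2 is exactly score 8).
* `balanced` — uniform class draw, for clean model-recovery experiments.

**Physiology.** The latent class drives three monotone parameters per
session: mean heart rate 60 + 30·class bpm (per-participant resting offset
σ = 1.5 bpm, constant across scenarios so within-participant ordering is
strict), RR jitter 60 − 15·class ms (heart-rate variability falls with
stress), and EEG alpha/beta power ratio 2.0 · 0.55^class (relative beta
rises with stress). These are deliberately strong effects: the recovery
tests ask whether the models can find them, not whether they are
physiologically calibrated.

**Waveforms.**

* ECG: beat times from an RR process (mean 60/HR, Gaussian jitter, 0.3 s
  refractory floor); each beat renders a 5-Gaussian PQRST template; plus a
  0.25 Hz baseline-wander sinusoid (amplitude 0.05) and white noise (0.02).
* PPG: each ECG beat, delayed by a 0.25 s pulse-transit offset, renders a
  two-Gaussian systolic/diastolic pulse; the green/red/infrared channels are
  gain-scaled copies (1.0/0.8/0.6) with independent sensor noise (0.03), so
  channels correlate near 1 in the noise-free limit.
* EEG: 1/f-power background (FFT spectral shaping of white noise) plus
  alpha- (8–12 Hz) and beta-band (13–30 Hz) filtered-noise oscillations
  whose power split follows the profile's alpha/beta ratio; total
  oscillation amplitude 0.8 relative to unit-variance background.

All waveform families are simple parametric stand-ins — they emulate the
class-dependent features (beat rate, beat-locked pulses, band-power shifts)
and first-order nuisances (wander, noise, early session termination), not
device-specific artifacts, motion corruption, ectopic beats, or inter-subject
morphology differences. Passing recovery tests therefore demonstrates that
the pipeline and models can extract class structure of this kind, not that
they reach any particular accuracy on real recordings.

Randomness fans out from the cohort seed via `numpy.random.SeedSequence`
spawns keyed by (seed, participant, scenario), so a single session is
regenerable in isolation and cohorts are bit-reproducible.

A configurable fraction (default 10%) of sessions is truncated (uniform
between 600 s and the nominal length) to emulate early puzzle completion.

## Preprocessing

Order: resample → filter → segment → normalize.

* **Fixed-grid resampling** (`scipy.signal.resample`, FFT band-limited):
  every channel maps to exactly 230,400 samples (15 min × 256 Hz)
  regardless of native rate or actual duration. Short sessions are
  time-normalized onto the grid rather than padded — the only reading under
  which every experiment yields the same sample count. A consequence: a
  truncated session's frequencies are stretched by nominal/actual duration.
* **Butterworth band-pass**, order 4, zero-phase (`sosfiltfilt`; the
  effective magnitude response is |H(f)|²): PPG 0.5–5 Hz, ECG 5–15 Hz,
  EEG 0.1–15 Hz. Order and zero-phase application are this package's
  choices (standard biosignal practice, preserves morphology).
* **Segmentation**: 10-s non-overlapping windows → 90 segments × 2560
  samples per session; floor semantics drop any trailing remainder
  (230,400/2560 divides exactly).
* **Normalization**: per-segment, per-channel z-score (statistics are local
  to the segment, since normalization follows segmentation). Constant
  channels are zero-filled with a warning.

Labels are per-session (one questionnaire per trial) broadcast to all 90
segments. Channel stacking order is PPG1, PPG2, PPG3, ECG, EEG restricted
to the requested modalities.

## Pretext transformations

Applied to segmented, normalized windows; the pretext task is 6-way
classification (original, noised, scaled, negated, flipped, permuted):

* noise: iid Gaussian, μ=0, σ=0.01;
* scale: ×1.1;
* negation, horizontal flip: involutions;
* permutation: 20 non-overlapping pieces of 64 samples (¼ s at 256 Hz),
  placed uniformly by slack distribution (guarantees disjointness without
  rejection), contents rearranged by a random derangement — no piece stays
  put, which is the strongest learnable signal; plain permutation is a
  config flag. Piece positions are shared across channels.

Time warping is deliberately not implemented. An alternative formulation
(per-transform binary heads instead of one 6-way head) exists in the
literature; the 6-way head was chosen as the simpler design.

## Models

All models map (channels × 2560) to 3 logits and accept 1/3/4/5-channel
input. They are implemented on a small numpy layer kernel
(`stresskit.nn`: Conv1d via im2col GEMM, LSTM with full BPTT, BatchNorm,
max/global pooling, Adam) with analytically derived gradients, verified
against central differences in the test suite.

* **StressNeXt**: 1×1 conv projection to width W, then four multi-kernel
  blocks — parallel convs with kernels 1/3/5/7 at equal width, combined by
  elementwise **addition** (not concatenation), then batch-norm, ReLU and
  stride-2 max pooling — then global average pooling and a dense head.
  Default W = 64 (the reference gives no widths).
* **LRCN**: two convs (width 64, kernel 7) + max pool, two residual blocks
  (width 64, kernel 3; pre-activation form `x + conv(relu(conv(x)))` so the
  zero-weight block is exactly the identity) separated by max pools, then
  two LSTM layers (hidden 128); the final hidden state feeds the dense
  head. No attention module, 1-D input only.
* **Self-supervised CNN**: encoder of three conv blocks
  (filters/kernels 32/32, 64/16, 128/8; two convs per block; max pool size
  8 stride 2), valid padding in blocks 1–2 and same padding in block 3.
  With 2560-sample input the feature lengths run 2529→2498→1246 (block 1),
  1231→1216→605 (block 2), 605→605→299 (block 3); the implementation
  asserts its computed shapes rather than hard-coding any intermediate
  length. Global max pooling yields the 128-feature embedding; a 6-way
  pretext head and the 3-way classifier share the encoder **by reference**,
  so pretraining updates are visible to the classifier; fine-tuning is full
  (no freezing; a flag exists).

Numerical choices: He-normal conv/dense init, LSTM forget-gate bias 1,
batch-norm momentum 0.3 (running statistics must converge within the short
training runs used here; with the textbook 0.1 the eval-time statistics lag
the trained weights on small datasets), cross-entropy loss, argmax ties
break to the lowest class index.

## Training and evaluation protocol

3-fold stratified cross-validation (segment-level stratification via
scikit-learn; every class needs ≥ k members, enforced with a clear error).
Adam, learning rate 0.001; 300 epochs for classifiers, 150 for pretext
pretraining (defaults; desk-scale runs lower them). The fold metric is the
**mean over all epochs' validation metrics** — unconventional, but it is
the protocol this package reproduces; `final_epoch` mode is provided.
Fold-level metrics are averaged again across folds; confusion matrices are
averaged across folds.

Metrics — accuracy and one-vs-rest macro-averaged precision/recall/F1 with
zero-denominator classes contributing 0 — are hand-implemented from the
defining equations and cross-checked against brute-force counting and
scikit-learn in tests. Macro averaging is the deliberate choice: under the
6030/1710/360 imbalance a constant class-0 predictor scores accuracy 0.7444
but macro-F1 ≈ 0.2845, reproducing the signature of a near-degenerate
classifier that weighted averaging would mask.

Segment-level folds leak participant identity between training and
validation; `stratified_folds(..., groups=participants)` provides the
honest grouped alternative. Scenario and difficulty breakdowns retrain on
each subset (independent-experiment framing) rather than slicing global
predictions; slicing is available by filtering the segment set.

## Desk-scale test configuration

The recovery tests use: 2 sessions per class (balanced, class heart rates
60/90/120 bpm), ECG only, every 3rd segment (180 segments, 60 per class),
StressNeXt width 16, LRCN conv width 16 / LSTM hidden 32, encoder filters
8/16/32, batch 32, ≤ 30 classifier epochs and 15 pretext epochs. These
sizes are the package's single-CPU reference configuration; the
architectures and protocol are identical to the defaults, only widths,
cohort size and epoch counts shrink.

## Known limitations

* Synthetic signals are far cleaner than real wearable data; absolute
  accuracies on this generator say nothing about accuracies on humans.
* The fixed-grid resampler time-dilates truncated sessions by design.
* The numpy kernel is single-threaded apart from BLAS matmuls; it is meant
  for desk-scale experiments, not large-scale training.
* Batch-norm tie-splitting in max-pool gradients distributes ties evenly,
  a measure-zero difference from picking one maximum.
* Pretext classes "original" and "noised" (σ=0.01 on unit-variance input)
  are intentionally near-indistinguishable; pretext accuracy saturates well
  below 1 for that reason.
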