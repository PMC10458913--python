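# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices, and the known limitations of `rdcnn-ecg`.

## Problem setting

Input is a rectangular matrix of pre-segmented heartbeats (default 187
samples at 125 Hz, ≈1.5 s per beat) with integer labels 0–4 for the five
beat classes N, S, V, F, Q.  R-peak detection and segmentation of
continuous recordings are out of scope; beats arrive already cut.  Class
frequencies in clinical corpora are extremely skewed (normal beats
outnumber fusion beats by two orders of magnitude), so rebalancing is a
first-class pipeline stage rather than an afterthought.

## Synthetic beat generator

Beat morphology is a sum of Gaussian bumps standing in for the P wave,
the QRS deflections and the T wave.  Positions and widths are fractions
of the beat duration; the constants table lives in
`synthetic_ecg._BUMPS`.  Class-specific distortions:

| class | morphology |
|---|---|
| N | P (0.18, σ 0.025, +0.15), Q/R/S (0.355/0.40/0.445, +1.0 R peak), T (0.62, σ 0.05, +0.30) |
| S | early attenuated P (0.09, +0.06), QRS and T advanced by ~0.05 |
| V | no P, wide high-amplitude QRS (R σ 0.030 ≈ 2× normal, ~180 ms full width), discordant (negative) T |
| F | pointwise mixture `(1−w)·N + w·V`, default w = ½, same jitter seed |
| Q | four irregular bumps with low correlation to all other classes |

V-class QRS width was chosen to match physiological premature
ventricular contractions (QRS ≈ 120–200 ms); making it wider turns the
complex into something a baseline tracker rightly treats as wander.

Per-beat jitter (seeded): bump centers ± 0.004, widths and amplitudes
± 5 % multiplicative, global gain ± 5 %.  A nearest-template classifier
on noise-free beats is exact (property-tested), so downstream
end-to-end claims are well-posed.

Noise processes (all amplitudes in the z-score-like units of the clean
templates, drawn in a fixed order for determinism):

* Gaussian noise of standard deviation `gaussian_sigma`;
* baseline drift: sinusoid (default 0.3 Hz — respiratory range) with a
  random phase;
* powerline interference: sinusoid (default 50 Hz) with random phase;
* motion artefacts: Poisson-placed Brownian-bridge excursions spanning
  50–90 % of the beat, scaled to `motion_amplitude`.  This emulates
  slow electrode-movement baseline jumps.  Short broadband bursts were
  deliberately not used: at single-beat scale they are spectrally
  indistinguishable from QRS energy, and no linear or median filter can
  remove one without the other;
* contact loss: with probability `contact_loss_prob`, one gap of
  `gap_length` samples is replaced by NaN sentinels and flagged in a
  boolean mask (arrays stay rectangular; nothing is deleted).

The generator emulates waveform *shape*, class-conditional morphology
and the standard artefact taxonomy.  It does **not** emulate inter-beat
rhythm context (RR intervals), inter-patient variability, lead
placement, or recording-device transfer functions — so passing tests
demonstrate pipeline correctness and the direction of preprocessing
effects, not clinical-grade performance on real corpora.

### Study conditions

The default study (used by the worked example, the end-to-end tests and
`scripts/acceptance.py`) is 200 beats per class under moderate mixed
noise: σ 0.15 Gaussian, 0.3 baseline, 0.1 powerline, 0.2 bursts/beat at
0.3 amplitude, 10 % contact loss.  The ablation study uses a heavily
imbalanced set (400/40/40/40/40) under roughly double that noise, the
regime where denoising and rebalancing both matter.

## Denoising

Five stages in fixed order, each individually toggleable, each acting
per beat:

1. **Contact-loss interpolation** — linear (default) or cubic over the
   observed samples; edge gaps take the nearest observed value.
2. **Baseline removal** — two-pass running median (0.25 s then 0.96 s),
   Gaussian-smoothed (σ 0.08 s), subtracted from the beat.  The short
   window rejects QRS spikes from the estimate; the long window tracks
   wander; the smoothing suppresses residual leakage of wide ventricular
   complexes.  The windows are longer than the 0.2 s/0.6 s pair
   customary for continuous records because a single 1.5 s segment gives
   the median far less isoelectric context: with the customary windows,
   clean-beat correlation after preprocessing capped at ≈0.95, versus
   ≈0.995 with these defaults (pure-drift residual stays at 6 % RMS).
   This stage also handles motion excursions, which are baseline jumps
   at beat scale.
3. **Powerline notch** — second-order IIR notch (default 50 Hz, quality
   30) applied forward-backward for zero phase, so beat shape is not
   skewed.  DC gain is unity; attenuation at half the notch frequency is
   below 3 dB.
4. **Wavelet shrinkage** — Daubechies-4, 4 levels, periodized transform
   (perfect reconstruction at threshold 0), universal threshold
   `σ√(2 ln N)` with `σ = median(|finest details|)/0.6745`, soft
   thresholding by default (hard available).
5. **z-normalization** — per beat, population standard deviation;
   constant beats map to zeros instead of raising.

Stage errors carry the offending beat index.  When the whole denoiser is
disabled (ablation arm), NaN sentinels are zero-filled so the network
still receives finite input.

## Rebalancing and splitting

* `subsample_majority`: uniform draw without replacement (e.g. normal
  class down to 5,000 rows).
* `resample_to_balance`: every class to a common target — without
  replacement when shrinking, with replacement when growing (e.g. all
  five classes to 20,000 rows).
* `split_train_test`: stratified by default, `floor(0.8·n)` per class to
  training, remainders to test; partitions disjoint and exhaustive.
* `kfold_indices`: seeded permutation split into k folds differing by at
  most one in size.

The pipeline rebalances **the training partition only**.  Balancing
before the split would let upsampled duplicates of one source beat land
on both sides and leak information into the test set; the alternative
ordering is available by calling the operations directly.  When no
target is configured, training classes are upsampled to the largest
class count present.

## Network

Architecture: `Conv1D(1→63, k=3)` stem (no batch norm, biases on) →
alternating residual and dense blocks (defaults: 2 + 2, two layers
each, 63 filters, kernel 3) with 2/2 max pooling between blocks →
global average pooling → Dense(64) + ReLU → dropout → softmax.

* Residual blocks follow `Y = F(x) + x`; when the input channel count
  differs from the branch width (after a dense block), the shortcut
  passes through a 1-tap projection convolution without bias.
* Dense blocks use full connectivity (every layer sees the block input
  and all previous layer outputs); a simplified `last-only` variant
  (chain the layers, concatenate input with the final activation) is
  selectable via `dense_connectivity`.
* Convolutions are one-dimensional with 3 taps — beats are 1-D signals.
* Initialization: He (fan-in) normal, seeded; identical seeds give
  bitwise identical models.

Training: categorical cross-entropy, Adam (default) or SGD, lr 0.001,
batch 64, ≤10 epochs, stratified seeded validation hold-out (10 %),
early stopping when validation loss fails to improve for 5 consecutive
epochs, best-validation weights restored.  Batch 16 and dropout 0.5 are
the main alternative settings worth trying; defaults are batch 64 /
dropout 0.3.  The implementation is plain NumPy: im2col convolutions,
analytic backpropagation (verified against central finite differences
to 3·10⁻⁷ relative error in the test suite).

The default configuration has 169,040 trainable parameters — deep
enough to solve the synthetic study in minutes on one CPU.  Block
counts, layer counts, filters and head width are all configurable for
larger budgets.

## Classifier

One binary soft-margin SVM per class (class vs rest), solver tolerance
1e-4, C = 1, linear kernel by default (RBF with γ = 1e-4 selectable);
prediction is the argmax of the per-class decision values with ties
broken toward the lowest class index.  The margin accessor reports
`d = 2/‖w‖²` — note the conventional geometric margin is `2/‖w‖`; both
are monotone in `‖w‖`, and the squared form is what this pipeline
defines.  Binary classifiers are fitted by scikit-learn's SVC; the
one-vs-all reduction, scoring and tie-breaking are this package's.

## Metrics

One-vs-rest reduction of the K×K confusion matrix gives per-class TP,
TN, FP, FN, and from them sensitivity (= recall), specificity,
precision and F1; macro averages are unweighted means over classes
present in the truth vector, and micro precision/recall coincide with
accuracy.  Cohen's kappa uses `P_o` = accuracy and
`P_e = Σ_k row_k·col_k / n²`; the degenerate case `P_e = 1` returns 1
when agreement is perfect, otherwise 0, and is flagged.  AUC is the
Mann-Whitney rank statistic (average ranks, so ties count ½),
equivalent to trapezoidal ROC integration.  All 0/0 rates report 0 with
a degenerate flag so tiny evaluations never crash.  Kappa and AUC are
cross-checked in the tests against brute-force pair counting and
scikit-learn.

## Determinism

Every stochastic operation takes an explicit seed; the pipeline derives
independent per-stage seeds from one global seed via a seed sequence.
A run manifest (resolved config + seed + input checksum) fully
determines a run, and re-executing from the manifest reproduces the
metrics report exactly on the same platform (single-threaded BLAS);
across platforms, accuracy reproduces to within a couple of percent.

## Problem sizes

The shipped studies are sized for quick, fully deterministic runs: the
end-to-end study uses 1,000 beats and the ablation grid 600 beats per
arm with a compact network (1 + 1 blocks, 24 filters).  Corpus-scale
count arithmetic (158,456 rows) runs on dummy one-column matrices, since
only label bookkeeping is exercised.

## Known limitations

* Synthetic beats are morphological cartoons; none of the results here
  transfer to clinical data without retraining and validation on a real
  corpus.
* The wavelet universal threshold assumes roughly white residual noise;
  strongly coloured noise will be under- or over-shrunk.
* Batch normalization statistics update during training even at zero
  learning rate, so "frozen" training is only exactly frozen for
  blockless configurations.
* Fusion (F) beats are mixtures of N and V by construction, and the
  residual confusions the pipeline makes are exactly V↔F — mirroring
  the class that is hardest in practice.
* The SVM step refits per class on the full feature matrix; for very
  large balanced training sets (10⁵+ rows) this becomes the slowest
  stage.
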