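# Methods

This note documents the model, the numerical and design choices behind the
implementation, what the synthetic-data generator does and does not emulate,
and the problem sizes the test suite runs at.

## Features

EEG trials (trials × channels × samples, µV) are analysed in the five
conventional rhythm bands — delta 1–4 Hz, theta 4–8 Hz, alpha 8–14 Hz,
beta 14–31 Hz, gamma 31–50 Hz. These edges follow the common convention for
62-channel emotion corpora; the band names are standard but the exact edges
are a package choice.

**Differential entropy (DE).** Each channel is band-passed with a zero-phase
4th-order Butterworth filter (applied forward and backward via
`sosfiltfilt`; the filter family is a package choice — only "band-pass per
band" is prescribed by the method). Within each sliding window the
band-limited signal is treated as Gaussian, giving

    h = ½ · ln(2πe·σ²)   (nats),

with σ² the window's sample variance (ddof = 1). The natural log is used
throughout; it is the base under which the closed form takes the `2πe`
shape. A constant window has undefined entropy and is rejected.

**Power spectral density (PSD).** Welch's method: Hann-windowed 2-s
segments, 50 % overlap (the overlap is a package default — a standard
variance/resolution trade-off), per-segment periodograms normalised by the
window energy, averaged over all segments, density scaling (power/Hz), no
detrending. The per-band feature is the **mean** density over the band's
frequency bins (not the sum); the convention is recorded in the tensor
metadata so either reading is reproducible. Trailing samples that do not
fill a window are dropped and logged.

Features are stacked to `(trials, bands, channels, windows)`; with 60-s
trials, 6-s windows and 62 channels this is the familiar `(n, 5, 62, 10)`
layout. The 32-channel binary layout is `(n, 32, 5, 60)`.

## Network

**Cross-modal attention (MCA).** Tokens are channels; a token's feature
vector is its window sequence (length `in_dim` = 10 or 60). Q/K/V are
linear maps to `att_dim = 32`; attention is `softmax(QKᵀ/√att_dim)V`; a
final linear layer maps back to `in_dim` so the fused map keeps the input
shape, and dropout 0.3 follows. One independent MCA per band; outputs are
stacked back on the band axis. Design choices where the method description
is open:

* the unidirectional variant takes queries from DE and keys/values from PSD
  (DE is the primary modality throughout);
* dropout 0.3 in both variants (only the bidirectional one states a rate);
* a single attention head (no multi-head fusion);
* the bidirectional variant `Atten(f1,f2,f2) + Atten(f2,f1,f1)` uses
  separate projection weights per direction.

**CBAM.** Channel attention: global average- and max-pooled descriptors
through a shared MLP `C → ⌈C/r⌉ → C` (C = 5 bands, r = 4, hidden 2 — the
integer division is resolved by ceiling so the bottleneck is nontrivial;
ReLU inside, biases kept, a bias-free mode is available in the config),
summed, sigmoid. Spatial attention: channel-wise mean and max maps
concatenated, 7×7 convolution with padding 3, sigmoid. Both gates lie in
(0, 1), so CBAM only attenuates; channel strictly precedes spatial.

**Convolutional feature extractor.** Two (Conv2d 3×3 → BatchNorm → GELU)
stages, 5 → 32 → 64 channels, padding 1; the convs carry no bias because
BatchNorm supplies the shift. Adaptive average pooling fixes the map to
(64, 31, 10) for every input geometry (downsampling the 62×10 grid,
replicating bins for the 32×3 segment grid).

**Sequence projection.** The time axis becomes the token axis; each of the
10 tokens is the flattened 64·31 = **1984**-dimensional column, linearly
mapped to d_model = 256 and layer-normalised.

**Conformer blocks (×2, independent weights).** Per block:
`x + ½FFN(x)` → pre-norm 8-head self-attention with residual →
depthwise-separable conv module with residual → `x + ½FFN(x)` → LayerNorm.
The FFN is `LayerNorm → Linear(256→1024) → GELU → Linear(1024→256) →
Dropout` (expansion 4); the conv module is `LayerNorm → depthwise conv
(kernel 5, same padding) → BatchNorm → GELU → pointwise 1×1 → Dropout`
(a canonical ordering of the stated components). Internal dropout 0.1. No
positional encoding — the conv module provides locality. Attention
projections carry no bias, and neither does the depthwise conv (BatchNorm
follows); these are standard conventions in pre-norm transformer stacks and
in BN-followed convolutions, and under them the reference configuration
counts **3,343,987 ≈ 3.34 M** trainable parameters. With every optional
bias enabled the same topology counts 3.3466 M; the bias-free conventions
are the configuration this package documents and tests.

**Classifier.** Global average pool over the 10 tokens, then
256 → 128 → 64 → n_classes with GELU and dropout (0.3, 0.2) on the hidden
layers; softmax output.

The network is implemented on the package's own seeded NumPy autograd
engine (`tanet.nn`): a tape-based reverse-mode Tensor, layer modules, AdamW
and gradient clipping. Every primitive's gradient is validated against
central finite differences in the test suite, and the 2-D convolution
against `scipy.signal.correlate2d`.

## Training

Loss: class-weighted, label-smoothed cross-entropy
`L = −Σᵢ wᵢ[(1−ε)yᵢ + ε/C]·log ŷᵢ`, batch-averaged, ε = 0.1. Weights are
inverse-frequency `wᵢ = N/(C·nᵢ)` (count-weighted mean exactly 1),
recomputed per training fold. Optimiser AdamW (β₁ = 0.9, β₂ = 0.999) with
decoupled weight decay; gradient accumulation over 2 micro-batches with the
loss scaled so the effective gradient matches one large batch; global-norm
clipping at 1.0; schedulers stepped per optimiser update over the whole run
(per-run rather than per-epoch cosine period — a package choice):

* cosine: `lr₀·(1+cos(πt/T))/2`;
* one-cycle: linear warm-up from lr₀/25 to the lr₀ peak over the first 30 %
  of updates, then cosine annealing to lr₀/100 (warm-up fraction, start and
  final values are package defaults; only the policy name is prescribed).

Protocol presets: the 3-class/62-channel protocol uses lr 0.002, weight
decay 1e−4, batch 96, one-cycle; the binary/32-channel protocol uses
lr 0.0005, weight decay 1e−3, batch 32, cosine. Early stopping monitors
validation accuracy with patience 15 (the patience and criterion are
package choices) and restores the best weights. Training is fully seeded:
one integer drives initialisation, dropout and batch order, and two runs
with the same seed produce identical histories. Mixed-precision training is
deliberately out of scope — it is a hardware optimisation that does not
change the method's outputs at tolerance.

## Protocols

**Subject-specific k-fold.** Per subject, stratified 5-fold partitioning of
that subject's trials; DE is z-scored per band and PSD square-root
transformed then z-scored, with statistics fitted on the training fold
only. The scalers are *instrumented*: they record a fingerprint of their
fit data, so the tests can prove no validation statistic leaked. Per-band
zero training variance falls back to centring only (logged). Metrics are
averaged with equal subject weight.

**Segment-level binary pipeline.** The raw layout `(n, 32, 5, 58, 4)` is
collapsed over its 4-segment axis by mean and extended to 60 time steps by
appending two copies of the mean of the last four steps. (The printed
58 → 60 extension is arithmetically underdetermined; this reading satisfies
the binding `(n, 32, 5, 60)` shape contract.) Bidirectional MCA fuses the
modalities per band *before* segmentation; the fused tensor is min-max
scaled to [0, 1] globally, cut into non-overlapping 3-step windows
(20 segments per trial — matching the ×20 label repetition), and affect
scores are binarised at 5 (≥ 5 → 1). The default scales the aggregate
before splitting, reproducing the "slice-first, then divide" benchmark
convention this pipeline exists to compare against; because that convention
lets test segments influence the scaling statistics, a leakage-safe mode
fits the min-max range on training trials only. The 9:1 split is stratified
and seeded; repeated runs use distinct seeds.

**Leave-one-subject-out.** Each subject in turn is the full test set;
scalers fit on the training subjects only.

**Ablation harness.** Variants replace exactly one module by an
identity-preserving stand-in: fusion → elementwise modality mean, CBAM →
identity, Conformer stack → identity (pooling then acts directly on the
projected tokens). All variants share folds and seeds; the table reports
mean ± sd accuracy/F1/kappa, the 95 % t-interval of accuracy, and paired
t-test or Wilcoxon p-values against the full model (self-comparison is
defined as p = 1).

## Metrics

Accuracy = trace fraction of the confusion matrix; F1 per class
`TP/(TP+½(FP+FN))`, macro-averaged for the 3-class task (the conservative
choice where the averaging rule is unstated); Cohen's κ = (P₀−Pe)/(1−Pe)
with Pe from the marginals (rejected when Pe = 1); micro-averaged
one-vs-rest ROC AUC by trapezoidal integration. Aggregation across
folds/runs uses the sample sd (n−1; a single run reports sd = 0) and sums
confusion matrices before row-normalising. A class absent from both truth
and prediction contributes F1 = 0 (logged).

## Synthetic data

The raw generator emulates the single property band-feature decoders
exploit: class-conditional band power. Each trial is one sinusoid per band
(frequency uniform within the band, random phase, amplitude =
10 µV × class gain) broadcast coherently over channels, plus Gaussian noise
(default 5 µV) with inter-channel correlation 0.3 achieved by mixing a
shared noise source. Defaults: 200 Hz / 60 s for the 62-channel layout,
128 Hz for the 32-channel layout. It does **not** model electrode geometry,
volume conduction, artifacts (EOG/EMG), non-stationarity or 1/f background —
so passing tests demonstrate that the pipeline recovers band-power structure
when present, not that it attains any particular accuracy on real
recordings.

The feature-level generator draws Gaussian tensors whose class means differ
by `effect_size` standard deviations on a fixed, class-disjoint subset of
band × channel cells (PSD obtained through a softplus to stay nonnegative).
At effect size 3 the classes are linearly separable (verified by a linear
discriminant oracle); at 0 every classifier is at chance, which the tests
use as a leakage guard on the training loop.

## Problem sizes used by the tests

The suite exercises the full-size reference model for architecture,
parameter-count and pipeline checks, and trains it on 500 synthetic trials
(3-sd separation) for the learning-sanity check and on 240 trials at
reduced epochs for the ablation table; unit-level training tests use a
topology-preserving shrunken configuration (8 channels, d_model 32,
1 block). These sizes are the package's choice of the smallest
configurations that still demonstrate each property.

## Known limitations

* CPU-only NumPy execution: full-protocol training at benchmark scale
  (thousands of segments, 100 epochs, 10 repetitions) is possible but slow;
  the package targets method correctness, not throughput.
* The benchmark headline accuracies require the original recordings, which
  are not redistributable; only the documented tensor layouts are accepted
  as external input.
* The segment-level protocol measures within-trial pattern discrimination.
  Segments of one trial can appear on both sides of the split; the
  leakage-safe scaling mode does not change that property, only the
  normalisation statistics.
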