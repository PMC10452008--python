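# Methods

This note records the model as implemented, the conventions and numerical
choices the code relies on, what the synthetic generator does and does not
emulate, and the design decisions taken where the architecture family
leaves the details open.

## Numerical core

All layers run on a small reverse-mode automatic-differentiation engine
over float64 numpy arrays (`ghostseg.autodiff`). Convolutions are im2col +
batched matmul with explicit backward passes (col2im scatter-adds);
transposed convolution is implemented as the exact adjoint of the strided
convolution, and the test suite verifies the adjoint identity
`⟨conv(x), y⟩ = ⟨x, convᵀ(y)⟩` as well as finite-difference gradients for
every structured op. Float64 was chosen over float32 because the matmul
is the bottleneck either way at the problem sizes this package targets,
and it makes tolerance bookkeeping (normalization limits, bit-exact
checkpoint round-trips) trivial. Inference runs under a `no_grad` context
so no graph is retained; a full 512×512 batch-2 forward pass with the
small width profile stays within a few GB of memory.

## Architecture conventions

* **Padding.** Every convolution uses "same" padding (odd kernels), so
  resolution changes only at the four explicit downsampling points
  (3×3/stride-2 max pool, two strided bottlenecks, 2×2 average pool) and
  the four stride-2 transposed convolutions. Input sizes must be divisible
  by 16; odd sizes at a stride-2 block are rejected rather than padded.
* **Ghost block.** `intrinsic = ceil(out/ratio)` (default ratio 2) maps
  from a point-wise primary convolution; the remaining maps from a 3×3
  grouped convolution with one group per intrinsic map. Convolutions are
  bias-free — the following normalization supplies the shift. When a
  bottleneck's middle ghost block carries the stride, the stride is
  applied by its primary convolution (kernel 3 there), and the cheap
  operation runs on the downsampled intrinsic maps; no extra
  normalization or activation sits inside the ghost split.
* **Bottleneck wiring.** `reduce (1×1 ghost) → SN → ReLU → middle → SN →
  ReLU → expand (1×1 ghost) → SN`, residual add, final ReLU
  (post-activation ResNet ordering; the diagrams this follows do not fix
  the SN/ReLU order in prose, so the choice is declared here). The
  internal width is `out/4`, the classical bottleneck reduction. Shortcuts
  are the identity when shapes match, else a strided 1×1 projection with
  its own normalization.
* **Switchable normalization.** Separate softmax weights for the mean and
  variance mixtures over {batch, instance, layer} statistics; layer and
  batch statistics are derived exactly from the instance statistics.
  Logits start at zero (an unbiased 1/3:1/3:1/3 mixture), γ = 1, β = 0.
  Running batch statistics (momentum 0.1, biased variance) replace the
  batch component at inference; instance and layer components are always
  computed from the input, so inference is deterministic per sample yet
  the layer remains finite and meaningful at batch size 1. A plain
  batch-norm variant (`normalizer="BN"`) is kept as the ablation axis.
  The stem uses the network-wide normalizer, so the default (SN) network
  satisfies the batch-1 finiteness property end to end.
* **MHSA.** 1×1 projections for q/k/v plus a learned 1×1 output
  projection; logits are `qᵀk/√head_dim` plus 2-D relative-position
  logits implemented as per-head bias tables over row offsets
  (`2H−1` entries) and column offsets (`2W−1`), a translation-invariant
  form of the content-position term used by bottleneck-transformer
  designs. Tables are sized to the configured bottleneck resolution
  (`patch_size/8`); inputs of any other size are rejected rather than
  silently interpolated. Default 4 heads.
* **Initialization.** He-uniform for all convolution weights, zeros for
  biases/β, ones for γ, zero SN logits, N(0, 0.02) relative tables.

## Loss

The class-wise dice loss is implemented in aggregated form: sums inside
the numerator and denominator of each class dice, ε (default 1e-6) in
both, and the patch label `y_p` gating between the foreground and
background terms. The loss is averaged per sample over a batch. As
typeset in some descriptions, the loss sums per-pixel ratios, which does
not reduce to a dice coefficient (a single-pixel "dice" saturates at 1/2
for a perfect prediction); that literal reading is available behind
`per_pixel=True` for comparison but is not used for training. Training
uses soft probabilities; binarization at 0.5 happens only for metrics.
ε = 1e-6 is small enough not to bias the dice on 512² patches (≥ 2.6e5
pixels) while keeping gradients finite at all-zero/all-one predictions.

## Metrics and aggregation conventions

DSC, JI and RVD are pixel-set metrics per image; the implementations are
tested against brute-force set-arithmetic oracles to 1e-12. Conventions:

* **Empty–empty masks**: DSC = JI = 1 (a correct all-negative
  segmentation); RVD is undefined for an empty annotation and such images
  are excluded from its aggregate.
* **DSC/JI/RVD aggregation**: averaged over images with a nonempty
  annotation. Against an empty annotation the dice is an all-or-nothing
  0/1, so negative images are judged instead by the classification
  metrics. The same convention is applied to the training/validation DSC
  reported by the training loop, for consistency with the test-set
  report.
* **Image-level classification**: an image's lesion score is its
  predicted foreground fraction; it is called positive when the fraction
  exceeds τ = 1e-3. τ was set against the 512×512 design patch (≈ 262
  pixels); on much smaller canvases the rule is correspondingly stricter.
  PA and precision come from this image-level confusion table
  (pixel-level pooled accuracy is reported alongside as `pa_pixel`);
  AUC is the midrank Mann–Whitney estimate of P(X₁ > X₀), equal to the
  trapezoidal ROC area, and is NaN for a single-class test set.

## Synthetic data

The generator draws, per sample, a pink textured background (low-frequency
Gaussian texture plus per-pixel noise around an H&E-like base colour) and,
with probability 0.5, a union of 1–4 rotated ellipses (radius 30–140 px on
the default 512 canvas, scaled down in the test profiles) rendered in
purple with its own texture; the mask records the ellipse union exactly
and the patch label is its nonemptiness. Every sample is a pure function
of (seed, index). The generator emulates the colour statistics, blob
geometry and class balance of tissue patches — it does **not** emulate
nuclear/glandular microstructure, stain variation between laboratories,
annotation noise, or ambiguous boundaries. Passing tests therefore
demonstrate that the architecture, losses, metrics and pipeline are
implemented correctly and that the model can learn blob segmentation from
scratch; they say nothing about accuracy on real pathology data.

Augmentation is a seeded draw from the 8 dihedral transforms (applied to
image and mask alike) plus mild colour jitter on the image only
(per-channel gain 0.9–1.1, shift ±10, probability 1/2).

## Tiling

Dense cropping tiles an image at a fixed stride with the final row/column
anchored at the image edge — full coverage, no invented pixels, no dropped
margins. Origins are 0-based (row, col) with half-open extents. Stitching
resolves overlaps by logical OR of binary predictions (recall-preserving);
probability-style averaging with a 0.5 threshold is available behind
`rule="mean"`. Both patch-level and stitched slice-level evaluation paths
exist because test-time protocol varies between studies.

## Training

SGD with momentum 0.9 and weight decay 1e-4 on every parameter, constant
learning rate 1e-2 (a cosine schedule is available behind
`lr_schedule="cosine"`), batch size 2, 500 epochs at full scale. Model
selection holds out 10% of training patches (when no explicit validation
set is given) and retains the best validation-DSC weights. Training on
positives only is exposed (`positives_only=True`) since the class-wise
loss also supports mixed training; mixed training is the default.
Checkpoints store all weights, running statistics and the exact network
configuration; save → load reproduces forward outputs bit-exactly.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` use the `cpu-small` profile
(stem 8, stages 16/32/64/128, 64×64 patches): an 8-patch overfit run
capped at 300 optimizer steps (batch sizes 2 and 1), a scaled-down
experiment training on 32 synthetic patches for 30 epochs and evaluating
a balanced 10:10 test set, metric oracles on 200 random 16×16 mask pairs,
and shape-contract forward passes at 64² and 512² (batch 1 and 2). These
sizes were chosen so the whole pipeline — generation, training,
prediction, evaluation — demonstrates its properties in about a minute
on a single CPU.

## Known limitations

* No GPU or mixed precision; the numpy engine is single-device and
  CPU-bound, so full-scale (512², width-1024, 500-epoch) training is out
  of practical reach here — the full profile is provided as configuration,
  not as a reproduced experiment.
* MHSA memory grows with the fourth power of the bottleneck resolution
  (attention is `(HW/8²)²` per head); 512×512 inputs are the intended
  ceiling.
* Relative-position tables pin inference to the training patch size by
  design (explicit rejection instead of silent interpolation).
* The image-level positive rule (fraction > 1e-3) is a declared
  convention, not a learned classifier; on small canvases it is strict.
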