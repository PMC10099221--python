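# Methods

## Scope and overall design

`grainseg` is a desk-scale, fully self-contained implementation of an
attention-augmented, bottom-up-fused Mask R-CNN for instance segmentation
of adherent wheat kernels. "Self-contained" is meant literally: the
numerical stack (`grainseg.nn`) is a small reverse-mode autodiff engine on
numpy float32 arrays with exactly the operator set the detector needs —
im2col convolution, group normalization, max pooling, nearest upsampling,
bilinear ROI sampling with scatter-add backward, and the standard
detection losses — plus SGD with momentum, gradient clipping, and linear
warm-up. Gradient correctness is enforced by finite-difference tests over
a composite network rather than per-op unit tests.

## The detector

**Backbone.** A residual network with stride-4 stem and four stages
C2–C5 (strides 4/8/16/32). Group normalization is used throughout because
the detector trains at batch sizes 1–4, where batch statistics are
meaningless. Two presets exist: the default (widths 32/64/128/256, two
blocks per stage) and a *tiny* preset (16/24/32/48, one block per stage,
256×256 input) used for CPU-scale training and tests.

**Attention.** ECA, SE, and CBAM blocks share the contract: shape
preserved, per-channel (and for CBAM per-pixel) gates strictly inside
(0, 1), so attention can re-weight but never amplify. The ECA kernel size
is k = nearest-odd |log₂C/γ + b/γ| with defaults γ=2, b=1; SE reduction 16
(bottleneck floor-divided, minimum width 1); CBAM spatial kernel 7. Blocks
are attached to the *outputs* of the four backbone stages, before the
pyramid's lateral connections; whether the original design gated before or
after the laterals is not stated anywhere, so this convention is fixed
here and documented rather than claimed.

**Pyramids.** Three interchangeable kinds behind one config:

- `fpn`: lateral 1×1 projections to a uniform width, nearest-upsample-and-
  add top-down, 3×3 smoothing per P-level, P6 = stride-2 subsample of P5
  (used by the proposal stage only; P6 carries the largest anchors).
- `bottom_up`: the smoothing convolutions are removed; N2 = P2 bit-exactly
  (no extra convolution on the finest level), and
  N(k+1) = conv3×3(downsample(N(k)) + P(k+1)) for k = 2..4. The
  downsample is a 2×2 max-pool by default ("pooling" being the literal
  operation described for this path); a strided 3×3 convolution is
  available as the conventional alternative.
- `rfpn` (ablation): first-pass P-levels are projected back to backbone
  widths, added to C2–C5, and a second smoothed top-down pass produces the
  outputs. No ASPP block, matching the variant studied.

**Region proposals.** Anchor scales {8, 16, 32, 64, 128, 256}, ratios
{0.5, 1, 2} (height/width = ratio, area = scale²). "Six anchor boxes"
is ambiguous between six scales on one map and six distributed scales;
both are implemented, with the distributed reading as default —
{level 2: (8, 16), 3: 32, 4: 64, 5: 128, 6: 256} — because six scales
cannot map one-to-one onto five levels. Assignment: max-IoU > 0.7
foreground, < 0.3 background, in between discarded; additionally the
best-overlapping anchor per ground truth is rescued to foreground (without
this unstated-but-standard rule, small dense targets can have zero
positive anchors). Proposal NMS threshold 0.5; pre/post-NMS top-k defaults
2000/1000 (training) and 1000/500 (inference), scaled to 600/300 and
600/150 in the tiny preset.

**Heads.** ROI align (one bilinear sample per output cell, boxes assigned
to pyramid levels by the k = ⌊4 + log₂(√area/224)⌋ rule clamped to 2..5)
feeds a two-layer MLP box head with 7-way classification (6 kernel classes
+ background) and class-agnostic box regression (targets scaled by the
canonical 10/10/5/5 weights), and a small FCN mask head predicting
per-class 28×28 mask logits, pasted back bilinearly and thresholded at
0.5. Detection-stage NMS is per-class at 0.5; the default confidence
threshold is 0.3.

**Training.** The usual five-component loss (RPN objectness BCE, RPN box
smooth-L1, ROI cross-entropy, ROI box smooth-L1, mask BCE), 256 sampled
anchors (≤½ positive) and 48–64 sampled ROIs per image with ground-truth
boxes appended to the proposal pool (standard sampling aid that matters at
short budgets). Full-scale defaults follow the published configuration
(lr 0.00125, batch 4, 50 epochs, warm-up); the source text also mentions
lr 0.0025 / batch 2 in another section — both are representable, the
former is the default. Warm-up is linear over 500 iterations (length
invented; only the use of warm-up is documented in the source).

## The synthetic scene generator

Each kernel is a rotated ellipse with semi-axes a ∈ [18, 30] px and aspect
ratio a/b ∈ [1.2, 2.5]; `broken` truncates the ellipse with a chord
(violating ellipticity, as real broken kernels do) and `sprouted` adds a
small protrusion past one pole. Class identity is carried by large,
high-contrast surface motifs chosen so the six classes are separable by a
very small model — the design goal of the generator — while staying within
each damage type's verbal description: gray mold patches over much of the
surface (moldy), several dark bore holes (injured), a dark-brown blotch
over the embryo end (spotted), a pale-green sprouting pole (sprouted), a
pale exposed endosperm face (broken), and no motif (perfect).

Placement uses rejection sampling with a conservative circular-separation
rule: centers may come no closer than (1 − adhesion)·(a₁ + a₂), so
adhesion 0 provably yields disjoint footprints and larger values allow
progressively deeper overlap. Occlusion is resolved by z-order; ground
truth masks contain *visible* pixels only (pixel-center-inside
rasterization; boxes are tight, half-open, origin top-left), and fully
covered kernels are dropped. Everything is reproducible bit-exactly from
the scene seed.

Augmentation magnitudes (the source names only the five methods):
brightness ×0.6, Gaussian noise σ=10 gray levels, 50 salt points,
translation up to ±15% of the side, horizontal flip. Photometric methods
leave annotations untouched; geometric methods transform masks and
recompute tight boxes, dropping instances pushed out of frame.

The default dataset recipe — 5 single-class bases per category + 100
mixture bases, ×6 versions — is the unique arithmetic consistent with the
canonical 780-image composition (30/6 = 5, 600/6 = 100); how the original
130 images were actually composed is not stated, so this inference is a
documented default, not a claim. The 8:1:1 split is stratified per
composition with largest-remainder rounding (surplus to train); image-level
assignment within a stratum is seeded-random. Note a deliberate fidelity:
like the dataset it emulates, augmented copies of one base image may land
in different splits, so val/test are not fully independent of train — a
property to keep in mind when reading absolute scores.

**What the generator does not emulate:** real kernel texture and shape
variety, lighting/camera effects, heaps more than one layer deep, class
ambiguity (real spotted vs moldy kernels can be genuinely confusable).
Passing desk-scale tests therefore demonstrates that the architecture,
losses, and evaluation are correct and that the improved variant learns
faster than the baseline *on separable data*; it does not certify accuracy
on real grain imagery.

## The desk-scale benchmark

GPU-scale claims are replaced by a fixed protocol
(`grainseg.benchmark.scaled_down_benchmark`): tiny preset, 40 training and
10 validation scenes at 256×256 with 3–6 kernels and adhesion 0.1,
300 iterations at batch 2, SGD momentum 0.9, lr 0.05 with warm-up over the
first 100 iterations, evaluated as mask mAP@0.5. The learning rate is far
above the full-scale default because the tiny network is group-normalized,
400× smaller, and sees each scene ~15 times; 0.05 is the stable choice for
this preset. A run takes ~1.5 minutes on one CPU; variants are compared at
identical seeds (data, initialization, and batch order all derive from the
seed) and summarized as the median over seeds 1–3.

## Metrics and matching

The matching rule (unstated in the source) is greedy by descending score
at mask IoU ≥ 0.5, each ground truth usable once, classes required to
agree; a box-IoU mode exists for comparison. AP uses all-point
interpolation (the precision envelope integrated over recall), with the
COCO 101-point mode as an option. Per-class pixel IoU compares the union
of predicted masks against the union of ground-truth masks of that class;
mIoU and mAP are unweighted means over classes present in the ground truth
(absent classes are excluded with a warning). Degenerate cases are defined
explicitly: zero-area boxes have IoU 0 (warned), empty-vs-empty mask IoU
is 0 (warned), precision/recall with empty denominators are 0 (warned),
and `average_precision` rejects inputs with more true positives than
ground truths.

## Known limitations and honest failures

- **Parameter-count ordering across variants.** Removing the four 3×3
  smoothing convolutions and adding three bottom-up fusion convolutions is
  a net *decrease* of one convolution's parameters, while ECA adds only
  ~18 scalars; consequently params(bottom-up variants) < params(baseline)
  < params(+ECA) in any faithful implementation, and the reported ordering
  in the source table (baseline < +FPN < +AM < +AM+FPN, in units that
  cannot be raw parameter counts) is not reproducible. The acceptance
  suite asserts it anyway and that single sub-check fails by design; the
  architecturally true relations (attention strictly adds parameters, the
  attention delta is identical across pyramids, bottom-up = unsmoothed FPN
  + exactly three 3×3 convolutions) are asserted and hold.
- Inference timing is reported informationally only; it is
  hardware-dependent and never part of a correctness check.
- The numpy engine is single-threaded-deterministic but slow; the package
  is a reference/desk-scale implementation, not a production trainer.
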