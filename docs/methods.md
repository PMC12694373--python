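# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, the numerical choices, and what the
synthetic-data experiments do and do not show.

## Adaptive focal loss

The loss operates on IoU-aware classification targets: for an element
matched to a ground truth, the target in its class channel is the IoU of the
*predicted* box with that ground truth (recomputed each step, detached); all
other channels are 0.  The base loss is varifocal,

    VFL(p, q) = [α·σ(p)^γ·(1 − q) + q] · BCEWithLogits(p, q),

with α = 0.75 (scale on negatives) and γ = 2.0 (focusing exponent).  Two
adaptive mechanisms sit on top:

* **Decay factor** `D_i = δ·(1 − exp(−i/λ))`, δ = 0.999, λ = 2000 steps.
  The exponent is read as `exp(−i/λ)`: with λ described as controlling the
  decay *rate* and the factor "progressively adjusted from near 0", the
  alternative reading `exp(−i·λ)` would saturate after a single step.
* **Dynamic threshold** `auto_iou = max(D_i·auto_iou_pre +
  (1 − D_i)·iou_batch, 0.2)`, updated once per optimizer step from the mean
  IoU of the batch's positive matches.  Early in training D_i ≈ 0, so the
  threshold tracks the batch; late in training it becomes a long-memory
  EMA.  `auto_iou` starts at its 0.2 floor before the first update, and a
  batch with no positives reuses the previous step's batch IoU.
* The **modulating weight** is 1 for q ≤ auto_iou − 0.1, `e^(1−auto_iou)`
  for auto_iou − 0.1 < q < auto_iou, `e^(1−q)` for q ≥ auto_iou (the "≥"
  branch takes the boundary tie).  For auto_iou ∈ [0.2, 1] all weights lie
  in [1, e^0.8].  The weight is a pure function of ground-truth quality, so
  the loss gradient with respect to the logits is exactly
  weight × ∂VFL/∂logit — verified by finite differences.

Two deliberate interpretive choices: `D_i` enters **only** the threshold
EMA and never rescales the loss (the description of its role is internally
contradictory; the explicit statement that it "does not scale the final
loss" wins), and the middle-band constant uses `auto_iou`, not the
element's own quality, exactly as the piecewise definition prints it.

## MSDRM

`DWR` performs regional residualization (3×3 conv–BN–SiLU) followed by
semantic residualization: parallel depthwise 3×3 convolutions at dilation
rates (1, 3, 5), summed, reduced by a pointwise conv, and added to the
input residual.

`DRB` runs a large-kernel convolution (default 7×7) in parallel with small
dilated branches (default 3×3 at dilations 1, 2, 3, depthwise), each with
its own BN.  The structural constraint `(k−1)·d + 1 ≤ large_kernel` makes
merging lossless: after freezing BN, each dilated kernel expands to its
sparse large-kernel equivalent (entries spaced by the dilation), BN folds
into the weights as `w·γ/√(σ²+ε)` with bias `β − γμ/√(σ²+ε)`, and the
branches sum into one kernel.  Merged and parallel inference agree to
~1e−15 relative in float64; the contract bound is 1e−5.

`MSDRM` combines them: regional features feed (a) a plain 3×3 dilation-1
conv for fine local detail, (b) two DRB sub-modules (large kernels 5 and 7),
and (c) a morphological MaxPool − MinPool filter (window 3, stride 1,
replicate padding) that highlights lesion edges; the paths are summed, pass
one shared BN, and add to the input residual.  Output width always equals
input width, so the block can replace a standard residual block in the two
deepest backbone stages.  The morphological path enters additively (the
only figure showing the fusion is ambiguous between an additive path and a
multiplicative gate; additive is implemented and noted here).  Defaults the
source design leaves open — DRB kernel sizes, the k = 3 window, SiLU
activation, "shared BN" read as one BN on the fused sum — are config-exposed.

## MSFPN

Laterals project the three backbone levels (strides 8/16/32) to one working
width (default 256; the toy harness uses 16).  The MSF focusing block aligns
the levels at the middle resolution — upsample (nearest, 2×) + 1×1 conv for
the high level, 1×1 conv for the middle, adaptive average pool + 1×1 conv
for the low — concatenates to F, applies four depthwise separable
convolutions with kernels {5, 7, 9, 11}, sums them to D, and returns
F′ = F + Conv₁ₓ₁(D).

The neck runs two focusing rounds.  Round 1: F₁'s upsample joins the low
lateral (→ RepC3 → X_RL) and its stride-2 3×3 conv joins the high lateral
(→ RepC3 → X_RH).  Round 2 focuses (X_RL, F₁, X_RH) into F₂, producing
X_UP′ and X_C′.  Context diffusion then fuses, residually, the low output
from (X_RL, X_UP′, X_UP) and the high output from (X_RH, X_C′, X_C); the
middle output is a projection of F₂.  The printed low/high fusion formulas
pair stride-8 maps with stride-32 maps, which cannot be concatenated; the
accompanying description — upsampled features diffuse to the low scale,
convolved features to the high scale — is the stride-consistent reading and
is what is implemented.  Likewise the printed round-1 high fusion names the
low-level map where only the high-level one is spatially compatible; a
`eq4_literal` flag restores the printed operand and deliberately trips the
alignment diagnostic, making the deviation explicit rather than silent.
Every concatenation asserts exact spatial equality — no silent cropping or
broadcasting.  RepC3 is a channel-harmonising projection plus a residual
re-parameterisable block (3×3 + 1×1 + identity, mergeable into one 3×3).
X_UP in the final high-scale fusion refers to round 1's upsample output (the
wiring diagram's arrows support this over a recomputed upsample).

## Imbalanced-dataset construction

Nine categories are partitioned uniformly at random (seeded) into three
ordered groups of three; slot proportions are assigned in printed group
order; each category retains `round_half_up(p·count)` samples drawn
uniformly without replacement under a single seeded generator, so identical
spec + seed reproduce identical subsets.  Statistics: share(c) =
100·count(c)/total rounded to one decimal, and the imbalance ratio divides
the largest rounded share by the smallest.  Three reference compositions
(exp1–exp3, severity 11.9:1, 22:1, 84:1) are bundled as fixed per-category
quantities: the base corpus they were drawn from is not recoverable from
their published counts, so the quantities are carried as inputs rather than
recomputed.  Rounding is half-up; the bundled quantities are consistent
with that rule.  A stratified per-category split utility complements the
sampler (the published train/test counts for these compositions do not pin
down a split rule, so a plain seeded stratified split is provided).

## Synthetic data

The generator emulates the two corpus styles: *clean* scenes (one leaf on a
near-uniform light backdrop — the laboratory setting) and *cluttered* scenes
(2–4 leaves over gradient backgrounds with distractor foliage and speckle —
the field setting).  Leaves are ellipses with category-coded lesion blobs
(colour, count and size derived deterministically from the category id);
every leaf yields exactly one box.  What it does **not** emulate: real
lesion texture, occlusion, lighting physics, camera noise, or the visual
subtlety that makes real disease categories hard to separate.  Passing
tests therefore demonstrate the *machinery* — losses, blocks, sampling,
evaluation — not field-level accuracy; no quantitative claim about real
imagery follows from them.

Augmentations: horizontal flip maps x → W − x exactly; 90° rotations
permute box coordinates exactly ((x, y) → (y, W − x) per quarter turn);
arbitrary-angle rotation (default ±15°, matching the small-angle style of
the source protocol) replaces each box with the axis-aligned hull of its
rotated corners clipped to the frame; blur and brightness leave boxes
untouched.  Splits always precede augmentation, and augmented variants
carry their source id so leakage is checkable.  The published 996 → 6022
training expansion is not an integer multiple of the four ops, so per-op
application counts are caller-controlled instead of hard-coded.  Salt noise
is pure salt — a seeded Bernoulli(p) subset of pixel positions set to the
maximum intensity — not salt-and-pepper.

## Evaluation

Greedy matching in descending confidence; each detection claims the
highest-IoU unmatched ground truth of its image and class; one ground truth
per true positive.  AP defaults to COCO's 101-point interpolation (all-point
available); mAP@0.50:0.95 averages thresholds 0.50–0.95 in 0.05 steps.  A
1e−10 slack in the recall-grid lookup keeps floating-point noise from
skipping exact precision–recall ties.  Classes with detections but no
ground truths are skipped with a warning; a class with no ground truths at
all raises.

## Detector harness

The harness is a deliberately minimal stand-in for a full detection
transformer: a four-stage convolutional backbone (MSDRM in the two deepest
stages), the MSFPN neck, and a per-scale 1×1 dense head predicting class
quality logits and box offsets against one square anchor per location (side
3×stride).  Assignment is per-location max-IoU with a 0.5 positive
threshold, plus a forced best-anchor match per object.  Box regression is a
squared error on encoded offsets; the classification loss is AFL (mean over
all elements, rescaled by the positive count for trainability at toy
scale).  Training defaults follow the source schedule where meaningful at
this scale — SGD with momentum 0.9, lr 0.01 annealed linearly to 0.001,
weight decay 5e−4 — with batch size 4.  The transformer encoder/decoder,
Hungarian matching and query selection of the full detector are out of
scope, as are its published accuracy figures, which require the real
curated imagery and GPU-scale training of a ~22M-parameter model.

Problem sizes for the bundled experiments were chosen to keep everything
CPU-friendly: 64×64 scenes, widths (8, 16, 24, 32), neck width 16 (≈128k
parameters), 200-step smoke runs on 50 images, and a 5-seed paired
AFL-vs-varifocal comparison on a 9:1 two-class set (18 vs 2 images, 150
steps).  At these sizes the paired comparison is directional only: the
median minority-class recall under AFL must not fall below the varifocal
baseline's; the two frequently tie.

## Numerical choices

Float64 throughout the engine, so merge equivalence and finite-difference
checks are sharp.  BCE uses the `max(x,0) − x·t + log1p(exp(−|x|))` form,
stable for any logit.  BatchNorm ε = 1e−5, momentum 0.1; merging requires
eval mode and fails loudly otherwise.  MinPool is −MaxPool(−x); pooling
uses replicate padding so edge responses are not inflated by zero padding.
Nearest-neighbour upsampling and integer-factor adaptive average pooling
keep the pyramid exact (levels must be exact 2× multiples; anything else is
rejected, not resized).  `round_half_up(x) = floor(x + 0.5)` for all count
rounding.

## Known limitations

The autograd engine is single-threaded numpy and intended for desk-scale
work, not production training.  The synthetic scenes make 9-way
classification nearly trivial in colour space yet the toy model still needs
hundreds of steps to separate categories — mAP from smoke runs is
diagnostic, not comparable to published detection scores.  The imbalance
sampler operates on image-level category assignments (an image's primary
category), not box instances.  The `eq4_literal` pathway exists only to
surface the printed-formula inconsistency and cannot execute.
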