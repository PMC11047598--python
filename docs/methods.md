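# Methods

This note records the models implemented, the choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
establish.

## Re-parameterizable blocks and exact fusion

A training-time block is a sum of linear branches followed by one
nonlinearity.  RepACID uses a 3×3 trunk plus 1×3 and 3×1 asymmetric
branches (the "skeleton" positions of the 3×3 kernel) and, when stride = 1
and in-channels = out-channels, an identity shortcut; RepVGG replaces the
asymmetric pair with a 1×1 branch.  Each branch ends in batch
normalization; branch convolutions carry no bias (the BN shift supplies
it), so the fused convolution holds the model's only bias.  Padding is
(1,1)/(0,1)/(1,0)/(0,0) for 3×3/1×3/3×1/1×1 so every branch produces the
same spatial output and the branch sum is well formed.

Fusion folds each BN into its kernel, embeds sub-kernels into 3×3 (middle
row, middle column, center; identity becomes the center Kronecker delta),
and sums kernels and biases.  The equivalence is exact in real arithmetic
and holds in float64 to ~1e-12; the test suite enforces 1e-4 relative
error over randomized blocks and whole models, which leaves three orders
of magnitude of headroom for accumulation effects at realistic widths.
Fusion uses the BN *running* statistics, i.e. it is an inference-time
transformation; converting a model in batch-statistics (training) mode is
meaningless and not offered.

Defaults: BN ε = 1e-3 (recorded in saved weights), SiLU activation
throughout — both configurable; these follow common single-stage-detector
practice, as the block definitions do not themselves fix them.  Grouped
convolutions are not supported (all blocks here are dense).  DBB-style
multi-path branches are documented but deliberately not implemented: they
buy accuracy at a large training-time cost and are not part of this
design.

## CSLA and gradient reparameterization

The quantization-friendly training path never builds the multi-branch
model.  A CSLA block replaces each branch BN with a *constant* per-channel
scale (s, h, v) and the identity BN with a *trainable* per-channel scale
initialized at 1.  Its exact single-operator twin starts from
W′(0) = s∘W_A(0) + h∘emb(W_B(0)) + v∘emb(W_C(0)) + I and multiplies every
gradient elementwise by the constant Grad Mult mask

    M[c, d, p, q] = s_c²
                  + h_c²            if p is the middle row
                  + v_c²            if q is the middle column
                  + 1               if (p, q) is the center and c = d and
                                    the identity branch exists.

The scalar special cases at the center position are 1 + s² + h² + v²
(c = d, identity) and s² + h² + v² (c ≠ d).  The positional structure
follows from which kernel entries each branch actually touches; a mask
that applied the three-term sum everywhere would not reproduce the CSLA
gradients off the skeleton, which the finite-difference oracle test
demonstrates.

Equivalence is exact for bias-free vanilla SGD (no momentum, no decay);
that is the form in which the tests verify 50-step trajectory identity for
a single layer and for a three-block nonlinear stack.  Production
training may enable momentum 0.937 and weight decay 5e-4, accepting that
equivalence then holds only heuristically (momentum commutes with the
constant mask only approximately, and decay not at all).  Weight decay is
applied *after* masking, so the masks scale only the data gradient.

Hyper-Search trains an auxiliary model — the backbone block layout with
trainable branch scales, global average pooling and a linear classifier —
on a proxy classification task built from rendered synthetic scenes
(default 10 epochs, seed-controlled), then freezes the learned scales into
masks stored in the weights file.  All scales initialize at 1, making the
auxiliary model an unscaled branch sum at the start.  When no searched
scales are supplied, blocks default to s = h = v = 1.

## Detector graphs and cost accounting

The baseline is the familiar nano-width single-stage layout: stem plus
four backbone stages with base channels (64, 128, 256, 512, 1024) × 0.25
and repeats (1, 6, 12, 18, 6) × 0.33 (rounded up), a CSP-style SPPF tail,
a bidirectional-fusion PAN neck (channels (256, 128, 128, 256, 256, 512) ×
0.25, repeats ⌈12 × 0.33⌉ = 4), and decoupled heads (1×1 stem, parallel
3×3 class/box towers, 1×1 predictions with 4 box channels) on strides
{8, 16, 32}.  The improved variant keeps the backbone (RepACID blocks
instead of RepVGG — identical at deploy) and removes the stride-8 head
with its neck up-branch: the second reduce layer, the second bi-fusion
module, the stride-8 fusion blocks, the re-descending 3×3 and the stride-16
fusion blocks fed by it.  The stride-8 backbone stage remains, since the
first bi-fusion consumes it.

Cost reports use the deploy form — branches collapsed, BN folded — which
is how re-parameterized detectors are conventionally compared (their
training-time parameter counts differ between block types; their deployed
graphs do not).  Parameters are exact counts of trainable scalars.  FLOPs
are 2 × multiply-accumulates over all convolutions at the stated input
size, with transposed convolutions counted at output resolution and bias,
normalization, activation and pooling operations excluded; the convention
is embedded in every `CostReport`.  Under it the baseline at 7 classes
totals 4,630,369 parameters / 11.342 G and the pruned model 4,394,806 /
9.821 G (deltas 0.236 M, 1.522 G) — the quantities
`scripts/acceptance.py` recomputes.

Anchor sets: 9 priors over three strides for the baseline, 4 over two for
the improved layout, with best-possible recall computed under the
per-dimension ratio rule max(w/a_w, a_w/w, h/a_h, a_h/h) < 4 (exclusive
bound; the threshold is the one used by the anchor-assignment family this
architecture inherits).  K-means uses Euclidean distance on (w, h) with
k-means++ seeding by default; a 1−IoU metric is available since both are
standard and printed anchors alone cannot adjudicate between them.  AP
uses 101-point interpolation by default with all-point integration behind
a flag, for the same reason.

## Desk-scale training

`fit` trains width-reduced builds of the real graph (default width 0.0625,
depth 0.1, two heads) at small input sizes — 128 px by default, the
smallest size at which the stride-16 grid still resolves the generator's
smaller objects.  The loop implements the full-scale recipe's shape:
initial learning rate 0.02 with cosine annealing to 1%, 3 warm-up epochs,
momentum 0.937, weight decay 5e-4, EMA (decay 0.99 at this scale), batch
size 8, optional mosaic.  Before training, box priors are re-clustered
from the training labels with K-means (one prior per head stride), the
same procedure that produced the two-head anchor set.

Label assignment is the simplified IoU/ratio assigner: each ground truth
goes to the stride whose scale band [s, 8s) contains its longest side
(clamped to the nearest band otherwise), choosing the better-fitting prior
when bands overlap, into its center cell plus the two nearest neighbor
cells.  The decode is bounded: center offsets 2σ(t) − 0.5 cells, extents
prior × (2σ(t))², matching the ×4 ratio rule.  The loss is varifocal
classification (IoU-quality targets, normalized by the number of
positives, focal weight held constant within a step, classification bias
initialized to −4 so scores start near the focal prior) plus CIoU box
regression (weight 2.5) through the analytic CIoU gradient, with β and
the focal weight treated as per-step constants — standard practice for
both losses.  DFL is implemented and exposed (n = 17 bins, weight 0.5 in
the combined loss) but the default head regresses 4 direct box channels,
matching the deployed prediction layout.

## Synthetic fixtures

The generator emulates the *structure* of camera-trap data, not its
appearance: high-resolution frames (2560×1920–4992×2808), textured
woodland-like backgrounds, one parametric animal silhouette per species
(ellipse composites with class-specific aspect ratio, head size, legs,
tail and coat pattern; seven classes), day/night illumination,
blur/noise/overexposure degradations, and object long sides spanning
0.12–0.45 of the short image dimension.  Default per-class image counts
are (191, 302, 253, 214, 346, 229, 239) — 1774 images, each class within
the 100–500 range typical of rare-species subsets.  The per-class 8:1:1
split draws val = round(0.1 n) and test = ⌊0.1 n⌋ per class with train
taking the rest, which yields 1423/177/174 under the default counts; the
augmentation expansion (horizontal flip with mirrored boxes, HSV jitter
with gains (0.015, 0.7, 0.4), Gaussian noise or 3×3 blur) adds exactly
three variants per image.  Out-of-bounds annotations are clamped with a
warning rather than dropped, preserving dataset size; mosaic drops boxes
whose visible area falls below 0.25 of the scaled original.

Scene geometry is a pure function of the scene seed and is stored
normalized, so labels survive rendering at any resolution; pixel rendering
is integer-based and byte-reproducible.  What passing tests show: the
training loop can learn to localize and score class-consistent shapes
under illumination and degradation variation (held-out mAP@0.5 ≈ 0.68 in
the 20-epoch single-class smoke configuration).  What they cannot show:
performance on real camera-trap imagery — real animals are deformable,
occluded, camouflaged and photographed with sensor noise the generator
does not model, and the full-scale accuracy figures require the real
dataset and GPU-scale training, which are outside this package's scope.

## Numerical notes and limitations

* Everything is float64 NumPy; convolution is im2col + matmul.  This is
  deliberate: exactness and inspectability over speed.  Full-size 640 px
  forwards run, but training is practical only for reduced widths.
* BN backward uses batch statistics; evaluation and fusion use running
  statistics.  `BatchNorm2d` momentum is 0.03.
* K-means re-seeds empty clusters at the farthest point and, when k equals
  the number of distinct shapes, provably returns those shapes.
* The trainer supports multi-branch (BN), CSLA and GR single-branch modes;
  mosaic is off by default in the smoke configuration (scenes contain one
  object and the collage's label bookkeeping is tested separately).
* Confusion-matrix rows are true classes; unmatched ground truths fall in
  the background column (missed), unmatched detections in the background
  row (false detections).
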