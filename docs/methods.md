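# Methods

`cytodet` implements a two-stage detector for cervical cytology images: a
dilated/grouped residual backbone (DC-ResNet style), feature-pyramid fusion,
anchors clustered from data under the 1−IoU distance, a balanced-L1
multi-task loss, and an RPN + RoI detection head — together with the
synthetic cytology generator used to exercise all of it.  Everything runs on
a small numpy layer library (`cytodet.nn`) with hand-derived backward passes
that are gradient-checked against central finite differences in the test
suite.

## Backbone

The backbone is a residual network whose stem is a 7×7/stride-2 convolution
with 64 channels followed by 3×3/stride-2 max-pooling.  Three *grouped*
bottleneck stages follow (multiplicities 3, 4, 6; grouped 3×3 with
cardinality g = 32; output widths 256, 512, 1024; entry strides 1, 2, 2),
then two *dilated* stages, each one variant-B block (a 1×1 convolution on
the shortcut) plus two variant-A blocks (identity shortcut).  Dilated
bottlenecks use a 3×3 with dilation 2 and padding 2, so by the output-size
relation

    y = floor((x − k − (k−1)(d−1) + 2p) / s) + 1

they leave the feature-map size unchanged.  Both dilated stages run at
stride 1: the point of dilation here is to grow the receptive field of the
deepest maps *without* further downsampling, so small cells keep spatial
support; a strided dilated stage would defeat that design and is rejected at
configuration time.  The five stage outputs F1..F5 therefore sit at strides
4, 8, 16, 16, 16.

The division in the size relation is floored, the universal convention of
convolution arithmetic; each realized layer is asserted against this
arithmetic in the shape-oracle tests.

The classifier head is global average pooling followed by three fully
connected layers (1024, 256, 2), each with dropout (rate 0.5 — a standard
value; the architecture fixes only that dropout is present).  Dropout is
disabled in evaluation mode, making inference deterministic.

**Layer counting.** `count_conv_layers` uses the depth-naming convention:
stem + every main-path convolution in the residual blocks + one for the
classifier head, with shortcut/projection convolutions excluded.  This is
exactly the rule under which the classic residual networks are called
"ResNet-50" (1 + 48 + 1) and "ResNet-101" (1 + 99 + 1); applied to the plan
above (19 bottlenecks × 3 convolutions = 57) it reports 1 + 57 + 1 = 59.
Alternative conventions (counting projections, counting each fc layer) are
available as flags and documented in the docstring; plausible counts for
this plan range 58–63 depending on the convention chosen.

Weight initialization: He-normal for convolutions, Xavier-uniform for fc
layers, BN scale 1 / shift 0; all draws come from a single seeded generator,
so builds are reproducible.  BatchNorm keeps running statistics with
momentum 0.9 (running ← 0.9·running + 0.1·batch) and uses them in
evaluation mode.  Input images are standardized per channel with constants
stored in the backbone config (defaults chosen for the synthetic imagery;
refit them when the data distribution changes).

## Pyramid fusion

Selected backbone levels (any ascending subset of F1..F5 of size ≥ 2,
spelled in the F-list notation, e.g. F[1,2,4,5]) are each projected by a
1×1 lateral convolution to a common width (default 256).  Starting from the
deepest selected level, the running map is upsampled to the next shallower
lateral's size and added; because the dilated stages preserve size, merges
among F3/F4/F5 are identity-upsample additions.  Upsampling is
nearest-neighbour — the merge is additive and followed by a learned 3×3
smoothing convolution (default on, toggleable), so the choice of
interpolant is second-order; nearest keeps the adjoint trivial.  Addition
rather than concatenation keeps every fused map at the configured width.

## Anchor clustering

Ground-truth boxes enter as (w, h) pairs imagined co-centred at the origin;
the distance between a box and a cluster centre is 1 − IoU of the two
centred rectangles.  `kmeans_iou` runs restarted Lloyd iterations
(k-means++-style seeding under this distance, restarts alternating with
random-subset seeding), with the per-cluster arithmetic mean of (w, h) as
the centroid update (median available for robustness).  Boxes are clustered
in pixel units; k defaults to 15 (three shapes for each of five levels) and
is reported together with the achieved average best-anchor IoU.

Two empirical facts shaped the implementation.  First, the mean (w, h) is
not the Fréchet mean of the 1−IoU metric, so a raw Lloyd step can slightly
*increase* the objective (observed increases ~3×10⁻⁴).  The algorithm
therefore tracks the best partition-mean state seen so far (the incumbent)
and reports its objective; the recorded per-iteration history is the
incumbent objective and is non-increasing by construction.  Second, the
globally optimal partition is frequently not a Lloyd fixed point under this
metric, so on small inputs (n ≤ 64 by default) each restart is refined by a
relocation/swap local search on the partition objective: move one box to
another cluster, or swap two boxes between clusters, whenever that lowers
the objective of the resulting mean-centre set.  With this refinement the
clustering matches exhaustive partition enumeration on every small random
instance in the test suite; the refinement cost grows roughly as n²k per
sweep, hence the size gate (configurable to "always" or "never").

Empty clusters are re-seeded from the box farthest from its assigned
centre.  Ties in best-anchor assignment resolve to the lowest anchor index.
Final shapes are sorted by area and dealt contiguously across pyramid
levels, smallest to the shallowest (highest-resolution) level; when k is
not divisible by the level count the shallow levels receive the extras.

## Loss

The detection loss is the two-term multi-task form

    L = (1/N_cls) Σ L_cls(p, p*) + λ (1/N_reg) Σ p* L_reg(t, t*)

with cross-entropy classification and a kernel applied coordinate-wise to
the (dx, dy, dw, dh) residuals of positive samples only (negatives
contribute nothing to regression).  λ defaults to 1. N_cls is the sampled
minibatch size and N_reg the number of sampled anchors, the standard
normalizers.  Box deltas use the usual parameterization dx = (gx−ax)/aw,
dy = (gy−ay)/ah, dw = ln(gw/aw), dh = ln(gh/ah); encode/decode round-trips
are exact to 1e−6.

Regression kernels:

* smooth-L1: 0.5x² for |x| < 1, |x| − 0.5 otherwise;
* balanced-L1:

      (α/b)(b|x|+1) ln(b|x|+1) − α|x|     for |x| < 1
      γ|x| + C                             otherwise

  with b solving α ln(b+1) = γ (derivative continuity at |x| = 1) and C
  fixed by value continuity there.  For the defaults α = 0.5, γ = 1.5 this
  gives b = e³ − 1 ≈ 19.0855.  The −α|x| term in the inner branch is
  retained from the loss's original formulation: without it the kernel is
  nonzero at the origin and loses C¹ continuity, contradicting the stated
  roles of α (inlier-gradient control) and γ (outlier-slope cap).  Both
  kernels are even, C¹, monotone in |x|, and their analytic gradients match
  finite differences to 1e−5 in the tests.

## Detection head

Dense anchors are laid out one per (cell, shape) with centres at
(i+0.5)·stride, and may extend past the image (clipped later).  Anchors are
matched to ground truth at IoU ≥ 0.7 (positive) / < 0.3 (negative), with
the best-anchor rule guaranteeing each overlapped gt at least one positive;
256 anchors are sampled per image at up to 1:1 positives:negatives (the
reduced benchmark uses 64).  Proposals are decoded, clipped, top-k'd (1000)
and NMS-filtered at 0.7 (keep ≤ 100); during training the gt boxes join the
proposal pool, a standard stabilizer.  RoI features are extracted by
align-style bilinear sampling, one sample per bin of a 7×7 grid, from the
pyramid level whose anchor shapes are nearest in log-area (the same
small-to-shallow ordering the anchors use).  The RoI head is two fc layers
(width 256; 128 in the reduced benchmark) with a 2-way classifier
(background / abnormal) and a single-foreground-class box refinement: only
abnormal cells carry detection labels, so "normal" is background to the
detector (the classifier head of the backbone is where the normal/abnormal
distinction is an explicit two-class problem).  RoI sampling uses threshold
0.5 and a 1:3 positive fraction (512 RoIs full-scale, 32 reduced).
Inference filters at score 0.05 and applies final NMS at 0.5.

The RPN uses a separate 3×3-conv head per pyramid level rather than one
head shared across levels: the layer library caches one forward pass per
layer instance, and per-level heads keep that invariant; at the benchmark's
scale the parameter difference is negligible.

Oracle injection points (`rpn_override`, `head_override`) replace either
stage's outputs with externally computed scores/deltas; the test suite uses
them to verify that ground-truth-derived outputs flow through proposals,
RoI extraction and postprocessing to reproduce the ground truth exactly
(mAP 1.0).

## Metrics

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), their harmonic mean,
F1 and accuracy; a zero denominator yields NaN ("undefined") rather than an
exception.  Detection AP uses greedy score-ranked matching (each gt matched
once) and all-points interpolation of the precision–recall curve; mAP
averages defined class APs.  The implementation is verified against a
brute-force PR enumeration on small instances.

## Synthetic generator

The generator emulates two regimes of liquid-based cervical cytology data:
multi-cell smear crops (default 800×800, several overlapping squamous
epithelial cells of widely varying size, aspect and orientation) and
single-cell crops (200×100) for classifier experiments.  Cells are rendered
as alpha-blended cytoplasm ellipses with an inner nucleus ellipse on a pale
background with Gaussian sensor noise.  The class rule is morphological: a
cell is *abnormal* iff its nucleus-to-cytoplasm area ratio exceeds a
threshold (default 0.2; normal cells draw ratios in 0.05–0.15, abnormal in
0.3–0.6), mirroring the enlarged-hyperchromatic-nucleus criterion of real
cytology.  Geometry is synthesized before rendering, so boxes (tight bounds
of the rotated cytoplasm ellipse) and labels are exact, and the label can
be re-derived from the rendered masks — a generator-fidelity invariant the
tests assert.  Placement is rejection-sampled under an overlap allowance;
an infeasible packing raises after bounded retries.

Datasets split 8:1:1 (val and test get ⌊n/10⌋ each, remainder to train)
with deterministic membership under the seed.  Slide-scale images are cut
into a non-overlapping 800×800 grid (reflect-padded at the edges); a box
lands in every tile it intersects, clipped, and is dropped when the clipped
area falls below 30 % of the original — boundary-cell handling is a policy
choice, recorded here.  Augmentation provides exact 90°-rotation and flip
transforms with box mapping, arbitrary-angle centre rotations, and
class-conditional replication (e.g. ×20 for normal, ×10 for abnormal
single-cell crops, equalizing an imbalanced two-class set).

What the generator does **not** model: staining texture and colour
variability, debris/inflammatory cells, out-of-focus blur, cell clusters
with shared cytoplasm, and the long-tailed morphology of real abnormality.
Tests passing on this data therefore validate the *mechanics* (shapes,
gradients, matching, ranking, bookkeeping) and the trainability of the
pipeline — not clinical detection performance.

## Training and the miniature benchmark

Both trainers are SGD with momentum 0.9.  The classifier schedule holds the
base rate (default 0.01, batch 32) until epoch 50, then divides by 10 every
10 epochs; the detector schedule (default base 0.00125, batch 6, weight
decay 1e−3) divides by 10 after epochs 16 and 22 — two successive drops.
Full-scale epoch counts are defaults in the experiment config, scaled by
`epoch_scale` for desk runs.

The miniature benchmark trains the whole two-stage pipeline from scratch at
desk scale: 128×128 scenes with three abnormal cells (cytoplasm semi-axis
10–24 px), 40 training and 10 held-out scenes, a reduced backbone
(stem 16 channels; stages 32/64/dilated-64 at strides 4/8/8), a 32-channel
pyramid over its three levels, k = 6 clustered anchors (two per level), and
300 single-image SGD steps at base rate 0.01 with a 20-step linear warmup.
Single-image steps occasionally produce outlier gradients early in
training, so gradients are clipped to a global L2 norm of 10 — without
clipping, float32 overflow can destroy the run.  These problem sizes keep
one training run well under a minute on one CPU core.

Runs trained under different regression kernels are compared on a
**kernel-free** validation objective — the mean absolute RPN regression
residual over positive anchors plus the mean anchor cross-entropy on
held-out scenes — because each kernel's own loss is precisely the quantity
the other run did not optimize and would bias the comparison.

## Numerical choices and degenerate inputs

float32 throughout the networks (float64 in gradient-check tests); BN
eps 1e−5; decode clamps dw/dh at ±20 so exp cannot overflow on untrained
predictions; NMS and sorting use stable order so ties resolve
deterministically; `conv_output_size` raises on non-positive results naming
the offending spec; metrics with empty denominators report NaN; AP with no
ground truth is undefined and excluded from mAP.

## Known limitations

* No ImageNet-scale pretraining and no claim about accuracy on real
  cytology data; the synthetic regime bounds what the tests can show.
* The detector processes images singly; there is no batched inference.
* RoI align samples one point per bin (sampling ratio 1); fine for the
  benchmark's map sizes, coarser than production implementations.
* The numpy layer library is CPU-only and unoptimized beyond im2col/einsum;
  full-scale (1000-epoch, 800×800) training is out of its intended range.
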