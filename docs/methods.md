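# Methods

## Problem setting

Counting greenhouse cherry tomatoes from RGB images is dominated by two
failure modes: fruit only a few pixels across, and occlusion by leaves,
stalks, and other fruit.  The standard box-regression losses built on IoU
are nearly blind to small localization errors on large boxes yet collapse
catastrophically on tiny ones — a 1 px shift of a 4×4 px box drops IoU from
1.0 to 0.6, and a 3 px shift to 1/7, while the same shifts leave a 45×45 px
box at 0.957 and 0.875.  This package implements the components designed
around that asymmetry, each testable in isolation, plus a synthetic scene
generator so everything runs with no external data.

## The Gaussian-Wasserstein box loss (EWDIoU)

A box R = (x_c, y_c, w, h) is modeled as a 2D Gaussian N(μ, Σ) with
μ = (x_c, y_c) and Σ = diag(w²/4, h²/4); the unit-Mahalanobis contour of
this Gaussian is exactly the ellipse inscribed in the box, encoding the
prior that evidence for the object concentrates at the box center.  For two
such Gaussians the squared Wasserstein-2 distance has the closed form

    W₂² = ‖μ₁ − μ₂‖² + ((w₁ − w₂)² + (h₁ − h₂)²) / 4,

equivalently the squared Euclidean distance between the 4-vectors
[x_c, y_c, w/2, h/2].  The tests verify this against the general
Bures–Wasserstein trace formula evaluated with dense matrix square roots.
W₂² is normalized into a (0, 1] similarity by exp(−W₂²/M); the scale
constant M defaults to 1.0 px² (the value that performed best in the
study this package re-implements).  Unlike IoU, the exponential similarity
degrades identically for a 4 px and a 45 px box under equal pixel shift —
the property asserted by the sensitivity tests.

The composite loss blends this with EIoU:

    EWDIoU = λ₁ · f_EIoU + λ₂ · (1 − exp(−W₂²/M)),  λ₁ + λ₂ = 1,
    f_EIoU = 1 − IoU + ‖b−b'‖²/(d_w²+d_h²) + (w−w')²/d_w² + (h−h')²/d_h²,

with (d_w, d_h) the extents of the smallest enclosing box.  Defaults
λ₁ = 0.7, λ₂ = 0.3.  Two notational points were genuinely open and are
resolved as follows: the exponent uses the *squared* distance W₂² (the
literal printed form), with `squared_exponent=False` switching to the
published-NWD convention exp(−√W₂²/M); and the α²(w, w') notation in the
EIoU penalty is read as (w − w')².  GIoU/DIoU/CIoU/SIoU follow their
original publications.  All losses run on plain arrays or on autodiff
tensors; an acceptance-level test checks analytic gradients against central
finite differences to 1e-4.

## Numerical engine

All trainable components run on a small reverse-mode autodiff engine over
NumPy arrays (`tinytomato.nn`): a tape of backward closures with full
broadcasting support, im2col+BLAS convolutions, fused batch-normalization
and SiLU backward passes, and Adam/SGD optimizers.  Every primitive's
gradient is tested against central finite differences.  Float32 is used
throughout the network path; the box-geometry API preserves float64 for
closed-form checks.

## Architecture components

**Space-to-depth (SPD) downsampling.**  Downsampling never strides: the
scale² phase sub-grids are gathered losslessly into channels (row-major
phase order (0,0), (0,1), (1,0), (1,1) at scale 2 — the order is a
serialization contract, fixed and tested), then a stride-1 convolution
(default kernel 3, configurable) compresses channels, with the constraint
out < scale²·in enforced.  The RGB stem relaxes that constraint
(`strict=False`) since any useful width exceeds 4·3 = 12 channels.
Bijectivity and value conservation are tested bit-exactly.

**Ghost / RepGhost blocks.**  The Ghost module produces half its channels
with a dense 1×1 convolution and half with a 3×3 depthwise "cheap"
operation.  The RepGhost module is reparameterized: at train time a
depthwise-conv+BN branch and a BN-only shortcut are summed; `fuse()` folds
both into a single depthwise kernel plus bias (BN statistics must be frozen
— fusing in training mode is refused).  Fusion equivalence is tested at
module and container level to 1e-5.  The RepGhost bottleneck reduces its
intermediate channels (mid ratio 0.25) relative to the Ghost bottleneck,
which gives the parameter ordering repghost ≤ ghost ≤ standard at the
channel budgets the detector uses (16+); at very narrow widths (< ~12
channels) the extra normalization layers can invert the first inequality.

**DASPPF.**  The pyramid-pooling block at the backbone exit: 1×1 reduction
to C/2, dilated 3×3 branches at rates (1, 3, 5), three cascaded 5×5
average pools (pyramid-pooling topology with average in place of max), an
optional global-average branch broadcast over the grid, concatenation, and
a 1×1 fusion.  Average pooling excludes padding from its divisor, so a
constant map passes through pooling unchanged.  The branch composition was
not fully pinned down by the source description; every element is a config
knob (`DasppfSpec`).

**CSAM attention.**  The input is split into channel halves.  The first
half receives channel attention — σ(MLP(maxpool) + MLP(avgpool)) with a
shared two-layer MLP (reduction ratio defaulting to 16 when divisible,
else the largest power of two that divides C/2) — merged by broadcast
*addition*, which is the literal printed definition of the ⊕ operation
(CBAM-style multiplication is available as `channel_merge="mul"`).  Then
non-local spatial attention: 1×1 query/key/value projections, softmax
affinity over all position pairs (row-stochastic, tested), modulation
h(x) ≡ 1, normalizer C(x) = 1 under the softmax form, residual addition.
The untouched half is summed back and a 1×1 projection restores the full
channel count; summation-then-restore was chosen over concatenation (both
"restore" the width — anyone reproducing parameter counts should note
this).  With the restore projection zero-initialized and the residual
bypass, the block is exactly the identity at insertion, so it can be added
to a trained host without changing its function.

## Detector assembly and toy trainer

The detector is a narrow anchor-free network: SPD-conv downsampling at
every scale change, C2f stages with RepGhost bottlenecks, DASPPF at the
backbone exit, a top-down neck with CSAM at the stride-16/32 junctions
(placing the quadratic-cost non-local block at coarse grids only), and one
head per stride {4, 8, 16, 32} — the stride-4 head exists specifically for
few-pixel fruit.  Box regression is direct (sigmoid center offsets within
the cell, exponential log-size, decoded to pixels) so the loss families act
on boxes exactly as defined rather than on a discretized distribution.
Target assignment is center-in-cell with size-based head routing (bins
double with stride); this deliberately minimal assigner isolates the
box-loss comparison from assignment heuristics.

Training defaults: Adam (β₁ = 0.937), lr 1e-3 with cosine decay to 0.1·lr,
weight decay 5e-4, batch 8–10, BCE class loss over all cells with positive
cells up-weighted ×15 (positives are only ~0.5% of cells at desk scale; the
up-weighting lets the class head converge within tens of epochs), box loss
weighted ×5 over positives, both normalized by the positive count.  NMS
defaults: confidence 0.25, IoU 0.7, class-wise.

## Synthetic scenes

The generator emulates the structure of a real greenhouse crop dataset
rather than its appearance: 640×640 default scenes (160 px for the
small-object study), three ripeness classes with strong imbalance (green ≫
red > yellow, count ranges (6–14)/(1–4)/(0–3) per default scene), fruit as
radially shaded ellipses in class hue bands, sizes down to 4 px, leaf-blob
and branch-stroke occluders drawn after the fruit, and the four difficulty
tags (tiny at box side ≤ 8 px; otherwise the occluder kind with the largest
pixel overlap, leaf winning ties).  Visible-area fractions and tags are
recomputable from the stored geometry.  Everything is deterministic under
the config seed; coordinates are continuous pixels with a top-left corner
origin, serialized to YOLO-txt at 6 decimals (round-trip error ≤ S·5e-7 px)
and Pascal-VOC XML at 2 decimals.

The augmentation suite applies a random combination of exactly three of six
operations (exposure, rotation, blur, brightness, mirror, noise); rotation
uses right-angle multiples so box transforms are exact ((x, y) → (S − y, x)
per clockwise quarter turn in corner-origin coordinates).  CopyPaste
transplants rare-class (red/yellow) instances between scenes with an
elliptical mask, rejecting locations more than 90% covered by existing
boxes.

What passing tests on these scenes does and does not show: the scenes have
honest small-object statistics, occlusion geometry, and class imbalance,
but none of the photometric complexity of field images (specular highlights,
foliage texture, lighting gradients, motion blur).  Results transfer as
statements about the *machinery* — losses, transforms, evaluator, training
dynamics — not as accuracy claims about real crops.

## The scaled-down loss study

`tinytomato.experiments.loss_family_comparison` trains paired detectors —
identical data, initialization, and batch order; only the box-loss family
differs — on 100 tiny-rich 160 px scenes for 18 epochs and scores mAP50 on
the tiny-instance subset of 25 held-out scenes (COCO-style subset scoring:
detections matched to non-tiny truths are ignored).  The problem sizes
(100/25 images, 18 epochs, width 0.25) were chosen once as the scale at
which the NumPy engine trains a usable detector in minutes on one CPU.  At
this scale absolute mAP values are small (the detector is narrow, the
objects are 4–8 px, and IoU ≥ 0.5 on a 6 px box tolerates well under a
pixel of error); the meaningful output is the paired difference, which
favored the Gaussian-Wasserstein loss in 3 of 3 seeds in our runs.

## Known limitations

- The engine is single-threaded NumPy: full-scale (640 px, width ≥ 1)
  training is out of reach; forward inference at 640 px works.
- Deploy-mode checkpoints store fused kernels but `load_checkpoint`
  reconstructs train-parameterized models; re-fuse after loading.
- The EIoU penalty normalizers make the loss slightly asymmetric in its
  arguments (the enclosing box is shared, the IoU term symmetric; the
  asymmetry enters only through which box is called ground truth in the
  penalty numerators — zero for identical boxes).
- Attention alternatives (SE/CBAM/GAM/scSE) are interface names only.
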