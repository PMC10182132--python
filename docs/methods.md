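# Methods

This note records the modeling choices, parameters, numerical details, and
known limitations of the package.

## Model

**Tiling.** Tissue/background segmentation thresholds the HSV saturation
channel: glass background is nearly achromatic while stained tissue is
saturated. The threshold is Otsu's by default, with a fixed-threshold
override; a pixel is tissue iff its saturation strictly exceeds the
threshold. A constant-saturation image yields an all-background mask.
Patches are non-overlapping squares on a fixed grid; partial border cells
are discarded so the grid is exactly `⌊H/p⌋ × ⌊W/p⌋`. A patch is kept when
its tissue fraction is at least `min_tissue_fraction` (default 0.25, a
package choice — tissue gating per patch is standard practice but the exact
rule is a free parameter). Coordinates are 0-based `(row, col)` with the
pixel origin at the top left.

**Features.** Patches are scaled to [0, 1] and standardized with the usual
ImageNet channel statistics. Two backbones are built in: the ResNet-50
feature topology (classification layer removed; 2048-d output; He-init from
a seed, or externally pretrained weights — e.g. from SimCLR — loadable from
`.npz`), and `tiny_test_cnn`, a three-stage strided conv net with a 32-d
output used for desk-scale experiments. Backbones process samples
independently of batch composition so features are bit-reproducible at any
batch size. All neural computation is NumPy; inference convolutions use
im2col in float32, and the trainable model runs in float64 on a small
reverse-mode autodiff core (`dtdsmil._autodiff`), so fixed seeds give
bit-identical reruns.

**Position embedding.** Two-axis sinusoidal embedding; each axis gets
`d_model/2` dimensions with interleaved sin/cos at frequencies
`base^(-2i/D)`, `base = 10000`. The normalizer `D` is the per-axis length
by default (`normalizer_dim="per_axis"`), matching the standard 2D
construction in which each axis is embedded independently; normalizing by
the full model width is selectable because the two conventions genuinely
coexist in the literature. Positions are grid column/row indices, not
pixels: the encoder's unit is the patch token.

**Encoder.** Single-level deformable self-attention in the Deformable-DETR
form. Tokens are linearly projected to `d_enc` and scattered to their grid
cells; non-tissue cells hold zeros and are marked invalid. Per query and
head, linear maps predict `n_points` continuous (x, y) offsets from the
cell-center reference point and `n_points` logits; attention is a softmax
over the points; values are read by bilinear interpolation (zeros outside
the grid) from a per-head slice of a bias-free value projection (bias-free
so empty cells stay exactly zero). Heads are concatenated and output-
projected. Blocks are post-norm residual with a GeLU FFN. Offsets and
logits are zero-initialized: an untrained layer attends uniformly to its
own location, so training starts from local sampling. Defaults
(`d_enc=256, n_layers=2, n_heads=8, n_points=4, d_ffn=1024, dropout=0.1`)
are desk-scale choices in line with the architecture family; every value is
configurable, and the synthetic benchmark uses a smaller instance (below).

**Dual-stream MIL head.** Instance scores are sigmoid probabilities
`c_idx = g_inst(f_idx)`; the critical instance is the argmax with ties
broken toward the lowest index. The query map Q is linear → ReLU → linear
(`d_q=128`), the value map V linear (`d_v=128`); attention logits are
`⟨q_i, q_crit⟩ / √d_q` (the scaling is a numerical-stability choice and can
be disabled), softmax-normalized over instances; `f_slide = Σ a_i v_i`;
`c_slide = g_slide(f_slide)` is again a sigmoid probability. The fused
score `c = ½(c_max + c_slide)` is therefore a probability and can be
thresholded directly.

## Training

Per-bag binary cross-entropy with Adam. The default loss supervises both
streams, `½[BCE(c_max, y) + BCE(c_slide, y)]` (`dual_bce`), consistent with
the dual-stream lineage; a fused-score variant is available. Gradients can
be averaged over mini-batches of bags; an optional cosine learning-rate
schedule with linear warmup is provided. Optional regularizers: dropout in
the encoder, weight decay, Gaussian input jitter, and coordinate
re-drawing (below). An optional stratified validation split supports early
stopping on validation AUC with parameter snapshotting. Training is
single-threaded and deterministic given `random_state`.

## Evaluation statistics

* **AUROC** is computed in the Mann-Whitney form via average ranks, so ties
  receive half credit.
* **DeLong CI**: placement values (structural components) of the positive
  and negative score sets give the AUC variance
  `S10/m + S01/n`; the normal-approximation interval is clipped to [0, 1]
  and collapses to the point estimate when the empirical variance is zero
  (e.g. perfect separation).
* **Threshold**: chosen on validation scores by maximizing Youden's
  J = sensitivity + specificity − 1. Candidate cuts are midpoints between
  consecutive distinct scores plus the two extremes (everything positive /
  nothing positive); ties resolve to the smallest threshold, and an
  all-equal score set returns the common value with a degenerate-case
  warning.
* **Confusion metrics** use strict `score > threshold` positivity. An
  undefined precision (no predicted positives) is reported as 0 with a
  warning flag.

## Node pipeline

Stage 1 is a pluggable detector behind the `Detection` contract. The
built-in reference detector thresholds tissue, labels 8-connected
components, and emits bounding boxes above a minimum area; it does not
discriminate lymph nodes from other tissue, and touching structures merge
into one box (documented limitation). Externally trained detectors (the
clinical setting uses a Faster R-CNN) drop in through a validated CSV
import. Boxes are half-open `[min, max)` at the 5× level; cropping at 20×
multiplies coordinates by 4 and clips to the raster with a warning. A node
crop with no tissue patches is classified benign and flagged. For
evaluation, detections are matched to ground-truth boxes greedily by
descending IoU with a 0.5 threshold, and unmatched detections
(misdetections) receive a benign true label; ground-truth nodes the
detector missed are not scored by the classifier stage (node-level metrics
are over detections, with recovery reported separately).

## Heatmaps

The probability map places each instance score at its grid cell on an
absolute [0, 1] scale; the attention map min-max normalizes the attention
weights per slide before placement, since attention is only meaningful
relatively within a slide. Non-tissue cells are missing (NaN; `NA` in CSV
export). Overlays upsample cells by nearest neighbor so each rendered block
corresponds bit-exactly to one patch — a deliberate auditability choice
over smoothed rendering. All-equal attention (including single-patch bags)
renders flat 0.5 and is flagged degenerate.

## Synthetic data

`gen_feature_bags` emulates the MIL assumption in feature space: negative
instances are `N(0, σ²I)` in `d` dimensions, positive instances are shifted
by `μ·u` along one fixed unit direction `u` drawn from the dataset seed;
positive bags contain `⌈ρ·N⌉ ≥ 1` positive instances at distinct grid
cells. The default benchmark is 300 bags (200 train / 100 held-out) of 64
instances on an 8×8 grid with `d=32`, half the bags positive, `ρ=0.1`,
`μ=2.0`, `σ=1.0`, generator seed 7. These are deliberately hard but
feasible conditions: the per-instance Bayes AUROC along `u` is
Φ(μ/√2) ≈ 0.92, a max-instance oracle reaches bag AUROC ≈ 0.94, and an
oracle aggregating all instance evidence ≈ 0.99, so beating 0.95 requires
the global stream to genuinely pool multi-instance evidence.

`gen_slide_image` renders saturated tissue disks on a gray background with
optional lesion disks of a distinct color inside positive nodes. Lesion
diameters respect the CAP size classes at the stated microns-per-pixel
(isolated tumor cells < 0.2 mm, micro 0.2–2.0 mm, macro > 2.0 mm); the
default 20 µm/px, 768² canvas and node radii 70–95 px let macro lesions
(> 100 px) fit inside nodes. What the renderer does **not** emulate:
H&E texture, nuclei, staining variation, pen markers, blur, or tissue
types other than disk-shaped nodes — so passing pipeline tests demonstrates
coordinate bookkeeping, detection plumbing, and learnability of a clean
color/texture contrast, not histological performance.

`split_dataset` uses floor/floor/remainder sizes for the 70:10:20 ratios
(chosen because it reproduces 590/84/169 for 843 items). Stratified mode
allocates each class by largest remainder under both the class totals and
the fixed split sizes.

## Benchmark study configuration

The reference benchmark model (`default_benchmark_model`) is a compact
instance: `d_enc=64, n_layers=2, n_heads=4, n_points=4, d_ffn=128`,
dropout 0.25, `d_q=d_v=128`, Adam lr 1e-3 with 5-epoch warmup and cosine
annealing over 100 epochs, batches of 8 bags, weight decay 1e-3, plus two
label-preserving augmentations matched to the bag generative process:
Gaussian input jitter (sd 0.5) and re-drawing each bag's instance-to-cell
assignment per presentation (instance placement is uniform in the
generator, so both are samples from the data distribution; the second also
prevents the encoder from memorizing position-feature conjunctions, which
is the dominant overfitting channel at 200 training bags). The problem
sizes throughout (bag counts, 64-instance bags, the compact encoder, 16
rendered slides in the node study) are chosen so a full study runs in
minutes on one CPU core.

The node-pipeline study trains a lighter instance (`d_enc=32, n_layers=1`,
30 epochs) on node crops from 10 rendered slides (patch size 64 at the 4×
upscaled magnification, `tiny_test_cnn` features), picks the threshold by
Youden's J on the training-node scores, and evaluates 6 held-out slides end
to end.

## Numerical details and degenerate inputs

* Autodiff runs in float64; softmax subtracts the (detached) row max; BCE
  clamps probabilities by 1e-12 inside the log.
* Bilinear sampling is differentiable in both map values and sampling
  locations; the weight derivative is piecewise linear (the measure-zero
  cell-boundary kink is ignored, as is standard).
* Argmax critical-instance selection is non-differentiable; gradients flow
  through the selected score only.
* Empty grids tile to an empty patch list with a warning; empty bags, single
  class label sets, and out-of-range scores raise typed errors
  (`dtdsmil.errors`).

## Limitations

* The dense grid representation wastes memory on sparse slides (multiple
  nodes far apart); accepted for architectural fidelity.
* The reference detector cannot separate touching nodes or discriminate
  tissue types; clinical use requires an external detector.
* Pyramidal WSI reading requires the optional `openslide` dependency; the
  tested path is plain PNG/TIFF rasters.
* No stain normalization, pen-marker removal, or blur handling.
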