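# Methods

`ctcforge` implements an end-to-end workflow for detecting circulating tumor
cells (CTCs) in microscopy images when box-annotated data are scarce:
copy–paste image synthesis turns classification-only cell patches into
detection training data, a transformer detector with scale and shape
adapters localizes and classifies cells, a sample-size-weighted loss mixes
real and synthetic sources, and a bootstrap evaluation suite quantifies
metric stability. This note documents the models, the defaults and the
reasoning behind the open design choices.

## Image synthesis by copy–paste

Cells are first segmented into binary instance masks `M`. From an image `I`
and a mask, a cutout `C = I · M` is cropped to the mask's tight bounding box
and given a per-pixel opacity channel (alpha = mask), so everything outside
the cell is transparent. Cutouts are augmented by the composition
*color jitter → rotation → scaling*:

- color jitter: per-channel multiplicative factors, default range [0.9, 1.1];
- rotation: uniform angle; exact multiples of 90° are applied as index
  permutations (no interpolation), other angles use bilinear resampling of
  both color and alpha with an expanded canvas;
- scaling: bilinear zoom, default factor range [0.7, 1.3].

Interpolation produces fractional opacity, so the patch support is defined
as `alpha > 0.5` and the patch is tight-cropped to that support; the support
cutoff is what makes the derived bounding box well defined. The augmented
cutout is alpha-composited onto a background at a uniformly sampled
position whose box has IoU ≤ `max_overlap_iou` (default 0.0) with every
occupied box — "unoccupied region" is formalized as a box-overlap bound
because nothing stronger is needed for non-overlapping ground truth. Any
real annotations already present on a background pre-seed the occupied
list, so pasted cells never collide with real cells. Finally i.i.d.
zero-mean Gaussian noise (default σ = 5 on the 8-bit scale) is added and
the result clipped to [0, 255]. Every emitted annotation corresponds to
exactly one successful paste; placement failures are skipped, and an image
with zero successful pastes is an error rather than a silent empty sample.

## Segmentation backends

Mask generation is pluggable. The default, dependency-light backend is
classical: Otsu global threshold, morphological opening (disk radius 2),
connected components, and an area filter (≥ 25 px). Polarity (`auto`)
chooses the threshold side with the smaller foreground fraction, since
cells are sparse. A promptable foundation-model backend (Segment Anything)
is exposed through the same `MaskSet` interface with both automatic and
box-prompt modes; it loads lazily and raises a clear error naming the
classical fallback when the package or checkpoint is absent. Overlapping
instances from the promptable backend are resolved by keeping
higher-confidence masks intact and subtracting them from later ones.

## Detection model

The detector is a one-stage dense-prediction network:

- **Patch embedding.** Non-overlapping P×P patches (P = 4) are linearly
  projected to D channels, plus a learned absolute positional embedding
  (stored on a fixed grid and nearest-neighbor resampled for other input
  sizes).
- **Backbone.** Four stages of windowed multi-head self-attention blocks
  with relative position biases, alternating regular and shifted windows,
  patch merging between stages; widths D, 2D, 4D, 8D at strides 4/8/16/32.
  Feature maps are zero-padded to window multiples and cropped after
  attention.
- **Scale adapter.** A feature pyramid: 1×1 lateral projections to a common
  width, top-down nearest-neighbor upsample-and-add, and a 3×3 smoothing
  convolution per level. It runs before the shape adapter, following the
  order in which the two modules are described.
- **Shape adapter.** Per pyramid level, a 3×3 deformable convolution whose
  per-location sampling offsets are predicted by a parallel 3×3
  convolution; sampling is bilinear with zero padding outside the frame.
  With zero offsets the layer is exactly a standard 3×3 convolution — this
  identity is the layer's main structural test and also its initialization
  (see Training).
- **Head.** A trunk of 3×3 convolutions shared across levels, then two
  per-location 1×1 projections: a softmax classifier over K classes plus
  background, and a 4-value box regressor. The head is dense (per-location)
  rather than RoI-based: the equations it implements are per-feature-map
  projections and a dense head is the minimal consistent structure.
- **Box parameterization.** Anchor-free: the four outputs are log-distances
  to the box sides in units of the level's stride, so a zero output decodes
  to the location's prior box (side 2×stride). Inference applies a score
  threshold (default 0.3) and one standard greedy per-class NMS
  (IoU 0.5, configurable).

Two presets exist. `paper-base` is the published "base" windowed-attention
configuration (embed 128, depths [2,2,18,2], heads [4,8,16,32], window 7)
with a 256-channel pyramid, per-level deformable adapters and a 4-conv
head; the head width (92) was chosen so the trainable-parameter total of
the full detector is 92.97 M, and `count_flops` reports an analytic
multiply-accumulate count covering convolutions, linear layers and
attention matmuls. `tiny-test` (embed 32, depths [1,1,1,1], window 4,
32-channel pyramid, 2-conv head) is the CPU-sized profile used by the test
suite and examples.

The numerical substrate is a small reverse-mode autodiff engine over numpy
(`ctcforge._tensor`): broadcastable arithmetic, matmul, softmax/layernorm,
im2col convolution, gather/scatter, and a fused bilinear-sampling primitive
for the deformable convolution. Every primitive is finite-difference
checked in float64; training runs in float32.

## Losses and target assignment

Single-source training minimizes `L = L_c + L_b`: mean cross-entropy over
sampled locations and a smooth-L1 box term (β = 1) summed over positive
locations and normalized by their count. Dense-head assignment: each
ground-truth box goes to the pyramid level whose canonical size (4×stride)
is nearest its longer side in log scale; locations whose centers fall
inside the box and within 1.5 strides of its center are positives (center
sampling — edge locations make poor regression targets). Negatives are
randomly subsampled at 3:1 to positives (at least 8 per level and image) so
the background class does not swamp the mean cross-entropy; the classifier
additionally starts from a background-prior bias so early training is not
flooded with false positives.

With mixed data the loss becomes `L = w_r·L_r + w_s·L_s + λ·R`, where
`w_r = N_r/(N_r+N_s)` and `w_s = N_s/(N_r+N_s)` are fixed by the *image*
counts of the two sources (counts per epoch, not instances), applied
per-batch with both sources present in every full batch. `R` is the
consistency regularizer: the mean squared difference between per-location
class probabilities for a synthetic image and a photometrically augmented
copy (noise + channel gain). Only photometric augmentations enter the
consistency pair, because the regularizer subtracts outputs elementwise and
therefore presumes spatial alignment. λ defaults to 1 (the regularizer is
presented unweighted) and is configurable.

## Training recipe

AdamW (decoupled weight decay 0.05), base learning rate 0.001, cosine
annealing with period 50 epochs over 100 epochs, batch size 16, multi-scale
input sizes (960², 1024², 1280²) sampled per batch — the paper-scale
recipe. The cosine schedule follows the standard CosineAnnealingLR
semantics (η reaches η_min = 0 at the period and rises back along the
cosine; no warm restarts). Scale/shape adapter and head weights are drawn
Xavier-uniform; the deformable offset branch is zero-initialized so
training starts at the standard-convolution limit. Each epoch covers each
dataset at most once, mixing batches in proportion N_r:N_s (≥ 1 sample from
each nonempty source per full batch). A seeded 20% validation split of the
real data is used to checkpoint the best-mAP weights. Divergence (non-finite
loss) aborts with a diagnostic.

The CPU profile (`tiny_train_config`) keeps the recipe but scales sizes
down: 15 epochs, batch 8, single 128² scale. The scaled-down study in the
acceptance tests trains the tiny model on 200 synthetic-microscopy fixture
images (single foreground class — matching the primary task, which is
single-class CTC detection) and evaluates 50 held-out images; with these
sizes one training run takes a few minutes on one CPU core.

## Evaluation

Greedy one-to-one matching per image and class at IoU ≥ 0.5: predictions in
descending score (ties prefer larger IoU, then input order) claim their
best unmatched ground truth; matched = TP, unmatched prediction = FP,
unmatched ground truth = FN. AP uses the full ranked list with the
all-point monotone precision envelope; mAP averages AP over classes present
in the ground truth. Confusion metrics (recall, precision, specificity,
accuracy) use predictions at the score threshold (default 0.3); 0/0 ratios
return NaN markers rather than raising.

Detection has no native true negatives, so specificity/accuracy need a
convention: per image, 20 seeded background candidate boxes with IoU < 0.1
against every ground truth are sampled; a candidate not overlapped
(IoU ≥ 0.5) by any retained prediction counts as TN, and overlapped
candidates are ignored (the offending prediction is already an FP). The
absolute specificity value therefore depends on the candidate count; the
convention is deterministic and documented rather than claimed comparable
to other tools' internals.

Bootstrap evaluation resamples the per-image records with replacement
(default 1000 resamples, seeded), recomputes the four confusion metrics and
mAP per resample, and reports mean, SD and quartiles per metric. A
single-image test set yields identical resamples and zero variance by
construction.

## Synthetic fixtures: what they emulate, and what they do not

The fixture generator renders ellipse-derived blobs with sinusoidal
boundary perturbation (random phase and frequency), class-dependent
stain-like color tints and texture, on smoothly shaded backgrounds with
Gaussian pixel noise — light-field (dark cells, bright background) or
fluorescence (bright cells, dark background) polarity. Defaults: 128²
images, cell semi-axis 6–14 px, eccentricity up to 0.6, boundary amplitude
0.15, foreground/background contrast 120 (constrained to exceed 3× the
noise σ so instances are detectable by construction), zero-IoU placement
with 100 rejection-sampling attempts per cell. Every instance carries a
pixel-exact mask and its tight box, making the fixtures usable as oracles.

These fixtures deliberately do *not* model staining chemistry, defocus,
overlapping or touching cells, debris, illumination artifacts, or the pixel
statistics of any real CTC dataset. Passing the scaled-down study shows the
pipeline — synthesis, assignment, optimization, decoding, evaluation — is
implemented coherently and can learn an easy, well-separated detection task
from scratch on a CPU; it says nothing about absolute performance on real
blood-sample imagery.

## Numerical and API choices

- Boxes are 0-based half-open `[x_min, y_min, x_max, y_max]` everywhere
  internally; COCO `[x, y, w, h]` only at (de)serialization.
- All randomness flows through explicitly passed `numpy` generators; the
  pipeline fans one run seed out to per-stage seeds via `SeedSequence`, and
  every fixture/synthesis op is a pure function of (config, seed).
- Cross-entropy probabilities are clamped to [1e-7, 1 − 1e-7].
- Box decoding clips log-distances to ±8 before exponentiation and clips
  boxes to image bounds; degenerate (zero-area) boxes are dropped at
  inference.
- The top-level `CTCDetector` follows the scikit-learn estimator protocol
  (constructor hyperparameters, `fit`/`predict`/`score`, fitted state in
  trailing-underscore attributes) so it composes with sklearn model
  selection; the module-level functions remain the low-level API.

## Known limitations

- Pure-numpy execution: throughput is roughly 0.1–0.2 s per 128² image per
  forward+backward on one CPU core; the paper-scale recipe (1024² inputs,
  100 epochs) is far outside this budget and is represented by the
  `paper-base` configuration for structural and complexity checks only.
- The promptable segmentation backend is untested against real weights in
  this repository (no checkpoint shipped); only its interface contract and
  fallback behavior are covered.
- Bootstrap resampling treats images as i.i.d. units; correlated imaging
  batches would need a blocked bootstrap.
- The analytic FLOP counter reports multiply-accumulates for convolutions,
  linear layers and attention matmuls; published FLOP figures for similar
  detectors often count subsets of these, so cross-tool comparisons need
  care.
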