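# Methods

## Problem and model

Diffraction-limited emitters appear in a fluorescence micrograph as
approximately Gaussian blobs of σ ≈ 1–2 px riding on a variable
background. `gridspot` casts their detection and sub-pixel localization
as a regression problem on *grid-cells*: the image is tiled into
`cs × cs` pixel cells and the network outputs, per cell, a spot
probability `p` and two within-cell offsets `(Δr, Δc)` normalized to
[0, 1). A cell can represent at most one spot; the cell-size therefore
trades classification class-imbalance (small cells: almost all cells
are background) against collision risk (large cells: two spots in one
cell, only one can be regressed). The collision fraction for uniformly
random spots grows with cell-size (property-tested); the default
`cs = 4` is a good operating point for typical smFISH-like densities,
and is configurable.

Coordinates are `(row, col)` with the origin at the top-left and the
center of pixel `(i, j)` at exactly `(i, j)`. Offsets are stored as
`(coord mod cs)/cs`, so encode→decode is exact to floating-point
precision when each spot occupies its own cell. On collision the spot
closest to the cell center is kept, remaining ties broken by row-major
coordinate order — deterministic and minimizing the expected
localization error of the kept spot.

## Architecture

A U-Net with a constant number of filters in every layer (wider deep
layers do not help this task; high-level semantics matter less than
precise low-level localization). Each encoder step is
[`convs_per_block` 3×3 conv+ReLU → squeeze-and-excitation → spatial
dropout → 2× max-pool]; decoder steps mirror the layout without
dropout, with nearest-neighbour upsampling and skip concatenation; a
skip connection carries the bottleneck input across the bottleneck
block. Because the output grid is `cs`-times smaller than the image, a
*second encoder* of `log2(cs)` blocks (same block layout as the
encoder) reduces the decoded full-resolution features to grid
resolution; a 1×1 convolution with logistic activation emits the three
channels, all bounded in (0, 1). Squeeze-and-excitation, the bottleneck
skip, and dropout are individually toggleable (`use_se`,
`use_bottleneck_skip`, `use_dropout`) so ablations can be re-run.

Valid input sides must be divisible by `2^unet_depth · cs`; inference
reflect-pads bottom/right to the next multiple and drops any prediction
falling in the padded margin.

The network runs on a small define-by-run autodiff engine
(`gridspot._nn`) written on numpy: convolutions are evaluated as nine
shifted BLAS matrix products in NHWC layout, float32 throughout. The
engine implements exactly the primitives the architecture needs and an
Adam optimizer with the AMSGrad correction. Gradients of every
primitive are verified against central finite differences in the test
suite (checked at smooth points; ReLU/max-pool kinks are excluded by
construction).

## Losses

* `J_class`: soft-dice on the probability channel, pooled over the
  whole batch, with smoothing ε = 1e-7 so that the empty/empty case has
  loss 0. Dice is used instead of cross-entropy because background
  cells outnumber spot cells by orders of magnitude.
* `J_loc`: RMSE of the offset channels restricted to cells where the
  ground-truth probability is 1. Each spot contributes the squared
  errors of both offset channels and counts once in `n`; an empty mask
  gives 0. Offsets are in within-cell units, which keeps the loss
  scale-free across cell-sizes.
* Total objective `J = J_class + 2·J_loc`: localization is harder than
  classification and benefits from the larger weight.

## Training

Defaults: cell-size 4, 64 filters, U-Net depth 3, dropout 0.3, batch
size 2, learning rate 1e-4, AMSGrad, 200 epochs. Choices the
published operating point leaves open, fixed here:

* **Normalization**: per-image standardization (subtract mean, divide
  by sd + ε), identical at train and test time — robust to the
  brightness variability between acquisitions.
* **Augmentation**: random flips and, for square images, 90°
  rotations of image and coordinates jointly, applied before grid
  encoding; on by default, seeded, toggleable. Flips around pixel
  centers map the sub-pixel sliver `(H−1, H)` out of frame; such
  coordinates are clamped back.
* **Checkpoint selection**: best validation *loss*, not validation F1 —
  at batch size 2 the F1 estimate is too noisy to select on.
* **Validation metric**: the F1 integral of the decoded predictions at
  probability threshold 0.5 is logged per epoch. 0.5 is the canonical
  operating point of a probabilistic output; the threshold is exposed
  everywhere but never tuned.
* No learning-rate schedule and no early stopping are used.

All randomness (shuffling, augmentation, dropout, initialization) is
derived from one integer seed; single-threaded runs are exactly
reproducible.

## Evaluation metric

At a distance cutoff `d`, predictions and truth are matched by solving
the assignment problem on the Euclidean distance matrix with entries
above `d` replaced by a prohibitive constant; pairs above the cutoff
are dropped afterwards, yielding a maximal matching under the cutoff
with minimal total distance. Comparison with the cutoff is non-strict,
which is required for a perfect prediction to score 1 at cutoff 0. F1 =
2TP/(2TP+FP+FN), defined as 0 when prediction and truth are both empty
(conservative convention; the degenerate case is flagged here because
conventions differ). The F1 integral evaluates F1 at 50 linearly
spaced cutoffs on [0, 3] px (both endpoints included), integrates by
the trapezoidal rule and divides by 3. Aggregates are mean ± sample sd
(ddof = 1, singleton sd reported as 0); the true-positive RMSE at the
3 px cutoff is undefined (NaN) for images without true positives and
such images are excluded from the RMSE aggregate.

## Synthetic data

The generator emulates fields of diffraction-limited emitters: spot
positions drawn uniformly with a minimum pairwise separation
(rejection sampling with a bounded consecutive-failure budget),
rendered as isotropic Gaussians evaluated pointwise at pixel centers
(no per-pixel area integration — adequate for σ ≥ 1 px), plus constant
background, optional Poisson resampling, and additive Gaussian read
noise. SNR here means peak spot amplitude divided by the Gaussian
noise sd; no claim of equivalence to any benchmark dataset's SNR
definition is made. Defaults describe a realistic smFISH-like tile:
128×128 px, 15 spots, σ = 1.5 px, amplitudes 80–120 over background
100, noise sd 10 (peak SNR ≈ 10), minimum separation 4 px.

What the generator does *not* emulate: non-Gaussian and anisotropic
PSFs, spatially varying background and autofluorescence, overlapping
emitters, motion blur, camera artifacts, and the labeling noise of
manual annotation. Tests passing on synthetic fields therefore
demonstrate the correctness of the pipeline and the learnability of
the task, not performance on any particular experimental dataset.

## Desk-scale training fixture

The learning tests use a reduced configuration chosen to train in a
few minutes on one CPU: 16 filters, U-Net depth 2, 20 epochs, learning
rate 1e-3 (raised from the 1e-4 default to converge within the short
schedule), on 80 synthetic high-SNR fields split 64/8/8. Under these
conditions the held-out F1 integral reaches ≈ 0.87 with a
true-positive RMSE of ≈ 0.34 px; the acceptance threshold (F1 integral
≥ 0.7, RMSE < 1 px) leaves margin for seed variation.

## LoG baseline

The classical comparison detector: the image is filtered with a
negated, scale-normalized Laplacian-of-Gaussian at
`σ = diameter/(2√2)` (the conventional blob-radius relation
`r = σ√2`; kernel truncation at 8σ keeps the discrete kernel
near zero-sum so flat backgrounds yield no response). Strict local
maxima of the response above a numerical floor become detections; the
peak response is the quality score and the position is refined per
axis by quadratic interpolation (offsets clipped to ±0.5 px).
Threshold selection mirrors manual-free tuning: grid search over blob
diameters; per image, qualities are normalized to that image's median;
twenty linearly distributed quantile levels (linspace(0, 0.95, 20) —
including 1.0 would discard every detection) of the pooled normalized
qualities are tried as absolute cutoffs; the (diameter, quantile
value) pair maximizing the mean F1 integral is selected. Whether the
"quantiles" of such a procedure are levels of the quality distribution
or linearly spaced cutoff values is an interpretation choice; this
package uses distribution levels.

## Dataset archive

A single zip file of `.npy` members plus `metadata.json`
(format-versioned): one image stack per split and one variable-length
coordinate table per image, float32 images and float64 coordinates
(lossless for labels). Members are written with fixed timestamps, so
archives with identical content are byte-identical — generation from
a fixed seed is reproducible to the byte. Splits use floor sizes for
valid/test with the remainder to train (never starving training);
default fractions 70/15/15. An optional per-image scalar stratum
(e.g. SNR) switches to a stratified split over quantile bins.
TrackMate label exports are read as pixel-unit positions with no
half-pixel shift (`POSITION_Y` → row, `POSITION_X` → col).

## Known limitations

* One spot per grid-cell: clusters denser than the cell-size are
  undercounted by design; choose a smaller cell-size for dense data.
* The numpy engine is CPU-only and single-device; full-scale training
  (64 filters, depth 3, hundreds of images, 200 epochs) is possible
  but slow — the package targets method correctness and desk-scale
  experiments.
* Only single-plane 2D images; multi-dimensional data are handled by
  predicting per slice/frame/channel and linking externally.
* Gaussian refinement assumes an isotropic PSF and falls back to the
  network coordinate when the fit fails or moves farther than half the
  fitting window.
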