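# gridspot

Threshold-independent detection and sub-pixel localization of
diffraction-limited spots in fluorescence microscopy images.

Counting and localizing point emitters — single mRNAs in smFISH,
tagged particles in live-cell imaging — is classically done with
hand-tuned intensity thresholds on filter responses (e.g. a
Laplacian-of-Gaussian), adjusted image by image. `gridspot` replaces
that with a trained fully convolutional network: the image is tiled
into small *grid-cells* of `cs × cs` pixels, and for each cell the
network regresses three values — the probability `p` that the cell
contains a spot and the spot's within-cell offsets `(Δr, Δc) ∈ [0, 1)`.
Decoding a cell at grid index `(i, j)` yields the continuous coordinate
`(i·cs + Δr·cs, j·cs + Δc·cs)`, so localization precision is not
limited by the pixel grid.

## Model

The network is a U-Net with a constant channel width across all layers;
every encoder step is [three 3×3 convolutions → squeeze-and-excitation
→ spatial dropout → 2× max-pool], decoder steps share the layout
without dropout, and a skip connection crosses the bottleneck. A second
encoder then reduces the full-resolution features by `log2(cs)` further
pooling steps to the grid resolution, and a logistic 1×1 head emits the
three channels. Training minimizes

    J = J_class + 2 · J_loc

where `J_class` is the soft-dice loss on the probability channel
(robust to the extreme background/spot class imbalance) and `J_loc` is
the RMSE of the offset channels over ground-truth spot cells. Defaults:
cell-size 4, 64 filters, dropout 0.3, batch size 2, learning rate 1e-4,
AMSGrad, 200 epochs.

Evaluation uses the **F1 integral score**: predictions and ground truth
are matched by the Hungarian method at 50 linearly spaced distance
cutoffs on [0, 3] px, the F1-vs-cutoff curve is integrated with the
trapezoidal rule and normalized by the maximal area. The score is 1 for
a perfect prediction and 0 when no prediction lies within 3 px of any
true spot; it rewards detection and sub-pixel precision in one number.
Localization alone is reported as the RMSE over true-positive pairs at
the 3 px cutoff.

The package also ships a synthetic spot-field generator with exact
continuous ground truth, dataset tooling (TIFF/PNG images, plain or
TrackMate-export CSV labels, a partitioned train/valid/test archive),
and a LoG baseline whose quality threshold is selected automatically by
a diameter × quantile grid search. The network runs on a small
numpy-based convolution engine included in the package; no GPU or deep
learning framework is required.

## Worked example

```python
import gridspot as gs

# 80 synthetic smFISH-like fields: 128x128 px, 15 spots each,
# peak SNR ~10, split 64/8/8
params = [gs.SpotFieldParams(height=128, width=128, n_spots=15,
                             amplitude_range=(80, 120), background=100,
                             noise_sd=10, min_separation=8)
          for _ in range(80)]
archive = gs.generate_dataset(params, (0.8, 0.1, 0.1), seed=7)

# reduced network for a CPU-scale run
det = gs.SpotDetector(filters=16, unet_depth=2, epochs=20,
                      learning_rate=1e-3, seed=7)
det.fit(archive.x_train, archive.y_train,
        X_valid=archive.x_valid, y_valid=archive.y_valid)

report = gs.evaluate(det.predict(archive.x_test), archive.y_test)
print(report)
```

```
f1_integral 0.8721 ± 0.0171 | f1@3px 0.9715 ± 0.0203 | rmse 0.3440 ± 0.0500 px
```

On the eight held-out fields the detector finds 97% of the spots
within 3 px (F1@3px 0.97), places matched spots 0.34 px from the truth
on average (RMSE), and the combined detection+localization quality is
an F1 integral of 0.87.

The same pipeline is available from the shell:

```sh
gridspot simulate -o data/ --n-images 80
gridspot create --images data/ --labels data/ -o dataset.zip
gridspot config -o gridspot.yaml          # edit hyperparameters
gridspot train --archive dataset.zip --config gridspot.yaml -o model.npz
gridspot predict --model model.npz --input data/ -o pred/
gridspot evaluate --pred pred/ --truth data/
gridspot baseline --input data/ --labels data/ --diameters 3,5,7
```

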