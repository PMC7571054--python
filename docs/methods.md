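# Methods

## Model

The boundary classifier is a fully convolutional encoder–decoder.  All
convolutions are 3×3, stride 1, zero-padded so spatial size is preserved;
each block stacks **three convolutions with no activation in between**,
followed by one batch normalization and one ReLU.  This "linear conv stack"
layout is kept deliberately: it is the literal layer table of the
architecture, and it fixes the parameter count.  The encoder uses 32/64/128
filters with 2× max pooling after each block; a 128-filter bottleneck block
follows; the decoder mirrors with 128/64/32 filters, each block opened by 2×
bilinear upsampling; skip connections are **element-wise sums** joining each
upsampled tensor to the equal-channel encoder activation (128, 64, 32); a
final 32-filter block and a single 1-filter convolution + sigmoid produce the
probability map.  Three poolings require input sides divisible by 8;
`predict(..., auto_pad=True)` reflect-pads other sizes and crops the output
back.

Parameter accounting: convolution weights + biases, plus four parameters per
batch-norm channel (scale, offset, moving mean, moving variance).  Under this
convention the default model totals 1,138,081 parameters; counting only the
two trainable batch-norm parameters would give 1,137,121.

The layers are implemented directly in NumPy (float32, NHWC).  Convolutions
are lowered to BLAS matrix multiplies via im2col; their backward pass is the
transposed pair of multiplies plus a 9-shift scatter-add (col2im).  Bilinear
upsampling is expressed as dense separable interpolation matrices
(half-pixel-center convention), whose transpose is the exact backward
operator.  Max-pool gradients are split evenly among tied maxima.  Batch norm
uses momentum 0.99 and ε = 10⁻³ and switches to its moving statistics at
inference, making prediction deterministic.  Weights use variance-scaling
(fan-in) normal initialization seeded from a single integer; batch-norm
scale/offset start at 1/0.

## Objective and optimization

The loss is per-pixel binary cross-entropy with probabilities clipped to
[10⁻⁷, 1 − 10⁻⁷] before the logarithms.  It is implemented as the **mean**
over pixels so the default Adam learning rate is independent of image and
batch size; the summed form is `J * N` (`LossValue.total`).  The
sigmoid–cross-entropy pair is differentiated jointly: the gradient at the
logits is `(y − t)/N`, which avoids the numerically fragile ∂σ/∂x factor.
Adam runs at its standard defaults (10⁻³, 0.9, 0.999, ε = 10⁻⁷).  Batch size
defaults to 8; epochs are a free parameter (no stopping rule is imposed), and
one checkpoint is written per epoch.  Given one master seed the run is
bit-reproducible: the seed determines initialization and the per-epoch
shuffles.

## Synthetic mosaics and ground truth

Mosaic structures come in three families, drawn uniformly per sample:

* **Voronoi** — 2–10 centroids at distinct integer pixel positions; each
  pixel takes the label of its nearest centroid (Euclidean distance between
  pixel centers, ties to the lowest centroid index).
* **Random walk** — two monotone 8-connected paths, one advancing one row per
  step from the top/bottom edge with lateral jitter in {−1, 0, +1}, one the
  analogous left/right walk; their side-of-path indicators cut the image into
  2–4 cells.  A single-walk mode (2 regions) is available.  The jitter set is
  exposed so a degenerate straight-line walk can be forced.
* **Circular** — k ~ U{1..4} circles, centers uniform over the image, radii
  uniform in [min(H,W)/8, min(H,W)/3], painted in draw order (later circles
  overwrite earlier); layouts in which any label is fully covered are
  redrawn.

The ground-truth border band marks every pixel whose (2r+1)×(2r+1) Chebyshev
window (clipped at image edges) contains ≥ 2 distinct labels.  The default
radius r = 2 gives a 4-pixel band across a straight boundary — always more
than two pixels wide — and is implemented exactly as a max-filter ≠
min-filter inequality.  The radius is a configuration knob.

Each region is filled with an independently drawn, independently augmented
texture; regions may reuse a source texture, and independent augmentation
keeps such boundaries visible.  Augmentation composes (1) one affine warp
about the image center — rotation·shear·scale then translation, parameters
drawn uniformly from the configured intervals (defaults: rotation 0–360°,
translation ±12 px, scale 0.5–1.5×, shear ±30°), bilinear interpolation,
reflective padding, central crop to the mosaic size; (2) additive uniform
noise U[−A, A] with A ~ U[0, 0.02]; (3) exactly one operation from a
seven-item photometric menu (CLAHE, global histogram equalization, log
adjustment with gain 1, sigmoid adjustment with cutoff 0.5/gain 10, gamma
with γ ~ U[0.5, 1.5], Gaussian blur with σ ~ U[0, 5], inversion), all at
scikit-image defaults.  The stage order follows the order in which the
operations are usually described; nothing in the data constrains it.  Setting
the menu empty skips stage (3); disabling augmentation makes the chain the
identity.

Dataset builds derive one unique child seed per sample from the master RNG
and record it in a JSON-Lines manifest together with structure type and
texture ids, so any sample can be regenerated exactly.  Images are written as
8-bit RGB PNG, masks as {0, 255} single-channel PNG.

### Procedural fixture textures

Five seed-deterministic families (stripes, checkerboard, sinusoidal grating,
Gaussian-smoothed blob noise, cellular/Worley) stand in for photographic
texture collections so the full pipeline runs with no external data.  They
emulate the two properties the classifier actually exploits — stationary
local statistics inside a region and a statistical discontinuity across
regions — but not the scale hierarchies, lighting variation or semantic
content of photographic textures.  A passing learning test therefore
demonstrates that the architecture, objective and data plumbing learn texture
boundaries end-to-end; it does not certify photographic-grade accuracy, which
requires training at full scale on real texture datasets (the folder loader
and CLI support this, and nothing in the pipeline is specific to the
fixtures).

## Evaluation protocol

For each image the probability map is thresholded over a grid (default 101
evenly spaced values in [0, 1]; a pixel is an edge when probability ≥
threshold, so the conventional single-map cut at 50% is the grid's midpoint).
Per threshold: precision, recall, F-measure, and the Pratt Figure of Merit
with a = 1/9, where each predicted edge pixel's displacement d is its
Euclidean distance to the nearest true edge pixel (computed by a distance
transform).  Degenerate conventions: precision = 1 when nothing is predicted,
recall = 1 when the truth is empty; FOM = 1 when both maps are empty, 0 when
exactly one is.

Curves are macro-averaged (per-image metrics averaged at each threshold);
micro-averaging (pooled confusion counts) is available behind a flag.  The
reported F curve is the mean of per-image F values by default, with
F-of-mean-precision/recall as the alternative.  The area under the mean PR
curve is the trapezoidal path integral taken along descending threshold —
recall is monotone in the threshold, and this convention stays well defined
when many thresholds collapse onto the same recall (e.g. saturated
predictors).  Summary scalars are the AUC-PR and the maxima of the mean F and
mean FOM curves over the grid.

## Scaled-down learning check

The test suite trains the full default architecture end-to-end at desk scale:
500 training and 50 held-out 64×64 mosaics built from two procedural textures
(stripes, blob noise), all three structure families, geometric + noise
augmentation with the photometric menu disabled — photometric invariance is a
data-volume question, not an architecture question, and 500 mosaics cannot
support it.  Three epochs at batch size 8 (a few minutes on one CPU) were
fixed after a pilot run: held-out max mean F reached 0.38/0.84/0.88/0.93
after 1/2/3/5 epochs, against ≈0.33 for an untrained network and ≈0.34 for a
Sobel gradient-magnitude baseline.  The test requires F ≥ 0.70 and strict
improvement over both baselines.

## Known limitations

* Boundaries between perceptually identical texture regions (same source,
  near-identical augmentation draws) are invisible in principle; the
  classifier merges such regions.
* The border-band ground truth is a morphological convention, not a geometric
  contour; FOM distances are measured to band pixels, not to the ideal
  1-pixel boundary.
* CPU training is practical to roughly 10³–10⁴ small mosaics; full-scale runs
  (10⁵ mosaics at 256×256) are supported by the same configuration surface
  but are compute-bound.
* Batch-norm statistics are computed per batch without cross-batch
  synchronization; very small batches give noisy statistics early in
  training.
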