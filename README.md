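# texsep — class-independent texture separation

`texsep` segments textured images by **pixel-wise binary boundary
classification**: every pixel is labeled either *border band* (a transition
between two or more texture regions) or *interior texture region*.  Because
the classifier predicts boundaries rather than texture classes, it needs no
predefined number of texture categories and generalizes to textures never
seen in training.  Typical users are researchers in biological and biomedical
image analysis (e.g. separating tissue regions in H&E-stained histology
sections), remote sensing, and texture-analysis benchmarking.

## The method

An encoder–decoder convolutional network with summed skip connections maps an
RGB image `x ∈ [0,1]^{H×W×3}` to a boundary-probability map `y ∈ (0,1)^{H×W}`:

* encoder: three blocks of three stacked 3×3 convolutions + batch-norm +
  ReLU (32, 64, 128 filters), each followed by 2× max pooling;
* a 128-filter bottleneck block;
* decoder: three blocks (128, 64, 32 filters) opened by 2× bilinear
  upsampling, with element-wise **sums** joining each upsampled tensor to the
  same-resolution encoder activation;
* a final 32-filter block and a 1-filter 3×3 convolution with a sigmoid.

The default model has exactly **1,138,081 parameters** (convolution weights
and biases plus four batch-norm parameters per channel).  Training minimizes
the per-pixel binary cross-entropy

    J = −(1/N) Σₙ [ tₙ log yₙ + (1 − tₙ) log(1 − yₙ) ]

with Adam at its default settings (lr 10⁻³, β₁ = 0.9, β₂ = 0.999).  The whole
network, including backpropagation, is implemented in NumPy (im2col
convolutions lowered to BLAS matrix products), so it trains on a plain CPU.

Training data are **procedurally assembled texture mosaics**: a random region
structure (Voronoi with 2–10 seeds, one/two crossing random-walk paths, or up
to four random circles) is filled region-by-region with independently
augmented textures (random rotation, translation, shear, scale, uniform
noise, and one of seven photometric operations).  The ground truth marks
every pixel whose 5×5 Chebyshev window contains two or more region labels — a
border band 4 pixels wide across a straight boundary.

Edge maps are scored with precision/recall over a probability-threshold grid,
the F-measure `F = 2pr/(p+r)`, the area under the mean precision–recall
curve, and the Pratt Figure of Merit

    R = 1/max(I_I, I_A) · Σᵢ 1/(1 + a·dᵢ²),   a = 1/9,

which penalizes missing, displaced and spurious edge points (R = 1 for a
perfect edge map).

## Worked example

```python
import numpy as np
from texsep import (AugmentConfig, TextureBoundarySegmenter, TextureLibrary,
                    evaluate_testset, generate_procedural_texture)
from texsep.mosaics import generate_mosaic

library = TextureLibrary([
    generate_procedural_texture("stripes", size=(96, 96), seed=1),
    generate_procedural_texture("blob_noise", size=(96, 96), seed=2),
])
aug = AugmentConfig(photometric_menu=())          # geometric + noise stages
samples = [generate_mosaic(library, (64, 64), seed=s, augment=aug)
           for s in range(550)]
train, test = samples[:500], samples[500:]

seg = TextureBoundarySegmenter(epochs=3, batch_size=8, random_state=1)
seg.fit(np.stack([s.image for s in train]),
        np.stack([s.target.mask for s in train]).astype(np.float32))
report = evaluate_testset(seg.model_, test, thresholds=np.linspace(0, 1, 21))
print(f"AUC-PR {report.auc_pr:.3f}  max mean F {report.max_mean_f:.3f}  "
      f"max mean FOM {report.max_mean_fom:.3f}")
```

On one CPU this trains in a few minutes and prints

```
AUC-PR 0.957  max mean F 0.885  max mean FOM 0.953
```

i.e. after three epochs on 500 small two-texture mosaics the classifier
recovers the boundary bands of held-out mosaics with a best mean F-measure of
0.89 and a Pratt Figure of Merit of 0.95 — far above an untrained network
(≈0.33) or a Sobel gradient-magnitude baseline (≈0.34), which cannot
distinguish texture boundaries from internal texture contrast.

The same pipeline scales to photographic texture datasets through the
command-line interface:

```bash
texsep generate --seed 1 -n 200 --out data/          # mosaics + ground truth
texsep train    --manifest data/manifest.jsonl --out run/
texsep predict  --checkpoint run/model.npz --out pred/ data/mosaic_*.png
texsep evaluate --checkpoint run/model.npz --manifest data/manifest.jsonl --out eval/
```

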