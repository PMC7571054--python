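"""The boundary-detection network: an encoder--decoder with summed skip connections.

The architecture is a fixed 38-row stack of 3x3 convolutions, batch-norm+ReLU
rows, 2x max-pooling, and 2x bilinear upsampling:

* encoder: three compression blocks of three stacked 3x3 convolutions
  followed by one batch-norm + ReLU, each closed by a 2x max pool; filter
  counts 32, 64, 128;
* a 128-filter bottleneck block;
* decoder: three expansion blocks (128, 64, 32 filters) opened by 2x bilinear
  upsampling, with element-wise *sums* joining each upsampled tensor to the
  same-resolution encoder activation (channel pairs 128, 64, 32);
* a final 32-filter processing block and a single 1-filter 3x3 convolution
  with a sigmoid, yielding a per-pixel boundary probability.

The network is fully convolutional: a model built at one size runs unchanged
on any input whose sides are divisible by 8 (three 2x poolings).  The default
configuration has exactly 1,138,081 parameters, counting convolution weights
and biases plus four batch-normalization parameters per channel (scale,
offset, moving mean, moving variance).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InputError
from .nn import Adam, BatchNorm, BilinearUp2, Conv3x3, MaxPool2, ReLU, sigmoid

_EPS = 1e-7

ENCODER_FILTERS = (32, 64, 128)


class _Block:
    """Three stacked 3x3 convolutions, then batch-norm + ReLU.

    The convolutions are deliberately stacked without activations in between;
    the single non-linearity sits after the block's batch normalization.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.convs = [Conv3x3(cin, cout, rng), Conv3x3(cout, cout, rng), Conv3x3(cout, cout, rng)]
        self.bn = BatchNorm(cout)
        self.relu = ReLU()

    def forward(self, x, training):
        for conv in self.convs:
            x = conv.forward(x, training)
        return self.relu.forward(self.bn.forward(x, training), training)

    def backward(self, grad):
        grad = self.bn.backward(self.relu.backward(grad))
        for conv in reversed(self.convs):
            grad = conv.backward(grad)
        return grad

    def parameters(self):
        out = []
        for conv in self.convs:
            out.extend(conv.parameters())
        out.extend(self.bn.parameters())
        return out

    @property
    def n_params(self):
        return sum(c.n_params for c in self.convs) + self.bn.n_params


class BoundaryNet:
    """Pixel-wise texture-boundary classifier (see module docstring).

    Parameters
    ----------
    input_size : (H, W)
        Nominal input size; both sides must be divisible by 8.  Prediction
        accepts any size satisfying the same constraint (the network is fully
        convolutional).
    seed : int
        Seeds the variance-scaling weight initialization.
    """

    def __init__(self, input_size: tuple[int, int] = (256, 256), seed: int = 0):
        h, w = input_size
        if h % 8 or w % 8:
            raise ConfigurationError(
                f"input size {h}x{w} must be divisible by 8 (three 2x poolings); "
                "pad or crop the input, or enable auto_pad at prediction time"
            )
        self.input_size = (h, w)
        self.seed = seed
        rng = np.random.default_rng(seed)
        f1, f2, f3 = ENCODER_FILTERS
        self.enc1 = _Block(3, f1, rng)
        self.enc2 = _Block(f1, f2, rng)
        self.enc3 = _Block(f2, f3, rng)
        self.bottleneck = _Block(f3, f3, rng)
        self.dec1 = _Block(f3, f2, rng)
        self.dec2 = _Block(f2, f1, rng)
        self.final = _Block(f1, f1, rng)
        self.out_conv = Conv3x3(f1, 1, rng)
        self.pools = [MaxPool2(), MaxPool2(), MaxPool2()]
        self.ups = [BilinearUp2(), BilinearUp2(), BilinearUp2()]
        self._cache: dict | None = None

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Batch forward pass: (N, H, W, 3) in [0,1] -> (N, H, W) probabilities."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[3] != 3:
            raise InputError(f"expected (N, H, W, 3) input, got shape {x.shape}")
        if x.shape[1] % 8 or x.shape[2] % 8:
            raise InputError(
                f"input size {x.shape[1]}x{x.shape[2]} must be divisible by 8"
            )
        e1 = self.enc1.forward(x, training)
        p1 = self.pools[0].forward(e1, training)
        e2 = self.enc2.forward(p1, training)
        p2 = self.pools[1].forward(e2, training)
        e3 = self.enc3.forward(p2, training)
        p3 = self.pools[2].forward(e3, training)
        b = self.bottleneck.forward(p3, training)
        s1 = self.ups[0].forward(b, training) + e3
        d1 = self.dec1.forward(s1, training)
        s2 = self.ups[1].forward(d1, training) + e2
        d2 = self.dec2.forward(s2, training)
        s3 = self.ups[2].forward(d2, training) + e1
        f = self.final.forward(s3, training)
        logits = self.out_conv.forward(f, training)[..., 0]
        return sigmoid(logits)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate from d(loss)/d(logits), e.g. (probs - targets) / N.

        The sigmoid and the cross-entropy are differentiated jointly, so the
        caller supplies the gradient at the logit level.
        """
        g = self.out_conv.backward(dlogits[..., None].astype(np.float32))
        g = self.final.backward(g)
        skip1 = g  # toward enc1 output
        g = self.dec2.backward(self.ups[2].backward(g))
        skip2 = g
        g = self.dec1.backward(self.ups[1].backward(g))
        skip3 = g
        g = self.bottleneck.backward(self.ups[0].backward(g))
        g = self.enc3.backward(self.pools[2].backward(g) + skip3)
        g = self.enc2.backward(self.pools[1].backward(g) + skip2)
        g = self.enc1.backward(self.pools[0].backward(g) + skip1)
        return g

    # -- parameters ---------------------------------------------------------

    def _blocks(self):
        return [
            self.enc1, self.enc2, self.enc3, self.bottleneck,
            self.dec1, self.dec2, self.final,
        ]

    def parameters(self):
        out = []
        for blk in self._blocks():
            out.extend(blk.parameters())
        out.extend(self.out_conv.parameters())
        return out

    @property
    def n_params(self) -> int:
        """Total parameter count (incl. batch-norm moving statistics)."""
        return sum(b.n_params for b in self._blocks()) + self.out_conv.n_params

    def make_optimizer(self, learning_rate=1e-3, beta_1=0.9, beta_2=0.999) -> Adam:
        return Adam(self.parameters(), learning_rate, beta_1, beta_2)

    # -- prediction ---------------------------------------------------------

    def predict(self, image: np.ndarray, auto_pad: bool = False) -> np.ndarray:
        """Per-pixel boundary probability map for one (H, W, 3) image.

        Inference mode: batch norm uses its moving statistics, so repeated
        calls are identical.  With ``auto_pad`` inputs whose sides are not
        divisible by 8 are reflect-padded and the output cropped back.
        """
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 3 or image.shape[2] != 3:
            raise InputError(f"expected (H, W, 3) image, got shape {image.shape}")
        h, w = image.shape[:2]
        ph, pw = (-h) % 8, (-w) % 8
        if (ph or pw) and not auto_pad:
            raise InputError(
                f"image size {h}x{w} not divisible by 8; pass auto_pad=True "
                "or pad/crop the image"
            )
        if ph or pw:
            image = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect")
        probs = self.forward(image[None], training=False)[0]
        probs = np.clip(probs, _EPS, 1.0 - _EPS)
        return probs[:h, :w]

    def predict_batch(self, images: np.ndarray) -> np.ndarray:
        probs = self.forward(images, training=False)
        return np.clip(probs, _EPS, 1.0 - _EPS)

    # -- introspection / serialization --------------------------------------

    def describe(self) -> list[dict]:
        """The architecture as 38 ordered rows (an auditable summary table)."""
        rows: list[dict] = []
        n = 0

        def add(layer: str, filters: int | None = None):
            nonlocal n
            n += 1
            row = {"number": n, "layer": layer}
            if filters is not None:
                row["filters"] = filters
            rows.append(row)

        def add_block(filters: int):
            for _ in range(3):
                add("Convolution 3 × 3", filters)
            add("Batch Normalization + ReLU Activation")

        add_block(32)
        add("MaxPooling")
        add_block(64)
        add("MaxPooling")
        add_block(128)
        add("MaxPooling")
        add_block(128)
        add("Bilinear Upsampling")
        add("Sum (outputs from layers 20 and 14)")
        add_block(64)
        add("Bilinear Upsampling")
        add("Sum (outputs from layers 26 and 09)")
        add_block(32)
        add("Bilinear Upsampling")
        add("Sum (outputs from layers 32 and 04)")
        add_block(32)
        add("Convolution 3 × 3", 1)
        return rows

    def dump_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"rows": self.describe(), "n_params": self.n_params}, indent=2))

    def _state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        names = ["enc1", "enc2", "enc3", "bottleneck", "dec1", "dec2", "final"]
        for name, blk in zip(names, self._blocks()):
            for i, conv in enumerate(blk.convs):
                state[f"{name}.conv{i}.w"] = conv.w
                state[f"{name}.conv{i}.b"] = conv.b
            for attr in ("gamma", "beta", "moving_mean", "moving_var"):
                state[f"{name}.bn.{attr}"] = getattr(blk.bn, attr)
        state["out_conv.w"] = self.out_conv.w
        state["out_conv.b"] = self.out_conv.b
        return state

    def save(self, path: str | Path) -> None:
        """Checkpoint all weights and moving statistics to a .npz file."""
        meta = dict(input_h=self.input_size[0], input_w=self.input_size[1], seed=self.seed)
        np.savez(path, **self._state_arrays(), **{f"meta.{k}": v for k, v in meta.items()})

    @classmethod
    def load(cls, path: str | Path) -> "BoundaryNet":
        with np.load(path) as data:
            model = cls(
                input_size=(int(data["meta.input_h"]), int(data["meta.input_w"])),
                seed=int(data["meta.seed"]),
            )
            for key, arr in model._state_arrays().items():
                arr[...] = data[key]
        return model


def build_model(input_size: tuple[int, int] = (256, 256), seed: int = 0) -> BoundaryNet:
    """Construct the default 38-row boundary network."""
    return BoundaryNet(input_size=input_size, seed=seed)


def count_parameters(model: BoundaryNet) -> int:
    """Total parameters: conv weights + biases, plus 4 batch-norm params/channel."""
    return model.n_params


def predict(model: BoundaryNet, image: np.ndarray, auto_pad: bool = False) -> np.ndarray:
    """Probability map for a single mosaic image (thin wrapper over the model)."""
    return model.predict(image, auto_pad=auto_pad)
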