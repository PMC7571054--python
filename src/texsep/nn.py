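"""Minimal NumPy neural-network layers with hand-written backpropagation.

Everything runs in float32 NHWC.  Convolutions are lowered to BLAS matrix
multiplies through im2col (`numpy.lib.stride_tricks.sliding_window_view`),
which is what makes CPU training of the boundary network practical.  Each
layer caches what its backward pass needs; `backward` must be called with the
gradient of the loss w.r.t. the layer output and returns the gradient w.r.t.
its input.  Trainable parameters are exposed as (array, grad) pairs for the
Adam optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(value, gradient) pairs updated by the optimizer."""
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero 'same' padding, with bias.

    Weights are stored as (Cin, 3, 3, Cout) and flattened to (Cin*9, Cout)
    for the im2col matmul; initialization is variance-scaling on fan-in.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        fan_in = cin * 9
        std = np.sqrt(2.0 / fan_in)
        self.w = rng.normal(0.0, std, size=(cin, 3, 3, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def parameters(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x, training):
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        # (N, H, W, C, 3, 3) view -> (N*H*W, C*9) copy; element order (c, ki, kj)
        view = sliding_window_view(xp, (3, 3), axis=(1, 2))
        cols = view.reshape(n * h * w, self.cin * 9)
        out = cols @ self.w.reshape(self.cin * 9, self.cout) + self.b
        if training:
            self._cols, self._shape = cols, x.shape
        return out.reshape(n, h, w, self.cout)

    def backward(self, grad):
        n, h, w, _ = self._shape
        gmat = grad.reshape(n * h * w, self.cout)
        self.gw[...] = (self._cols.T @ gmat).reshape(self.w.shape)
        self.gb[...] = gmat.sum(axis=0)
        dcols = gmat @ self.w.reshape(self.cin * 9, self.cout).T
        dcols = dcols.reshape(n, h, w, self.cin, 3, 3)
        dxp = np.zeros((n, h + 2, w + 2, self.cin), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, :, i, j]
        self._cols = None
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W).

    Trainable scale/offset plus moving mean/variance (momentum 0.99,
    epsilon 1e-3); inference uses the moving statistics, so prediction is
    deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.channels = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.moving_mean = np.zeros(channels, dtype=np.float32)
        self.moving_var = np.ones(channels, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def parameters(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    @property
    def n_params(self) -> int:
        # scale, offset, moving mean, moving variance
        return 4 * self.channels

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.moving_mean[...] = self.momentum * self.moving_mean + (1 - self.momentum) * mu
            self.moving_var[...] = self.momentum * self.moving_var + (1 - self.momentum) * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * inv_std
            self._xhat, self._inv_std = xhat.astype(np.float32), inv_std.astype(np.float32)
            return (self.gamma * self._xhat + self.beta).astype(np.float32)
        inv_std = 1.0 / np.sqrt(self.moving_var + self.eps)
        return ((x - self.moving_mean) * inv_std * self.gamma + self.beta).astype(np.float32)

    def backward(self, grad):
        xhat, inv_std = self._xhat, self._inv_std
        m = grad.shape[0] * grad.shape[1] * grad.shape[2]
        self.ggamma[...] = (grad * xhat).sum(axis=(0, 1, 2))
        self.gbeta[...] = grad.sum(axis=(0, 1, 2))
        dxhat = grad * self.gamma
        dx = (inv_std / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
        )
        self._xhat = self._inv_std = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x, training):
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0.0
        return out

    def backward(self, grad):
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool2(Layer):
    """2x2 max pooling, stride 2.  Gradient is split evenly among tied maxima."""

    def __init__(self):
        self._x: np.ndarray | None = None
        self._out: np.ndarray | None = None

    def forward(self, x, training):
        n, h, w, c = x.shape
        out = x.reshape(n, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))
        if training:
            self._x, self._out = x, out
        return out

    def backward(self, grad):
        x, out = self._x, self._out
        n, h, w, c = x.shape
        up = np.repeat(np.repeat(out, 2, axis=1), 2, axis=2)
        mask = (x == up).astype(np.float32)
        counts = mask.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
        gup = np.repeat(np.repeat(grad / counts, 2, axis=1), 2, axis=2)
        self._x = self._out = None
        return (mask * gup).astype(np.float32)


def _upsample_matrix(n_in: int, factor: int = 2) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel centers)."""
    n_out = n_in * factor
    src = (np.arange(n_out) + 0.5) / factor - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = (src - i0).astype(np.float32)
    m = np.zeros((n_out, n_in), dtype=np.float32)
    m[np.arange(n_out), i0] += 1.0 - w1
    m[np.arange(n_out), i1] += w1
    return m


class BilinearUp2(Layer):
    """2x bilinear upsampling as separable dense interpolation matrices."""

    def __init__(self):
        self._mats: dict[int, np.ndarray] = {}
        self._in_shape: tuple[int, ...] | None = None

    def _mat(self, n_in: int) -> np.ndarray:
        if n_in not in self._mats:
            self._mats[n_in] = _upsample_matrix(n_in)
        return self._mats[n_in]

    @staticmethod
    def _apply(mat: np.ndarray, x: np.ndarray, axis: int) -> np.ndarray:
        out = np.tensordot(mat, x, axes=([1], [axis]))
        return np.moveaxis(out, 0, axis).astype(np.float32)

    def forward(self, x, training):
        self._in_shape = x.shape
        out = self._apply(self._mat(x.shape[1]), x, 1)
        out = self._apply(self._mat(x.shape[2]), out, 2)
        return out

    def backward(self, grad):
        _, h, w, _ = self._in_shape
        out = self._apply(self._mat(h).T, grad, 1)
        out = self._apply(self._mat(w).T, out, 2)
        return out


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimizer with the standard defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        learning_rate: float = 1e-3,
        beta_1: float = 0.9,
        beta_2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta_1, beta_2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
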