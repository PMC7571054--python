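"""Training: binary cross-entropy objective and the Adam fitting loop.

The objective is the per-pixel binary cross-entropy

    J = -(1/N) sum_n [ t_n log y_n + (1 - t_n) log(1 - y_n) ],

where t_n in {0, 1} is the border/interior target and y_n in (0, 1) the
predicted boundary probability.  The mean (rather than the raw sum) makes the
default Adam learning rate independent of image and batch size; the sum is
recoverable as J * N.  Probabilities are clipped to [1e-7, 1 - 1e-7] before
the logarithms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InputError
from .mosaics import DatasetManifest, MosaicSample, load_manifest_arrays
from .network import BoundaryNet

_EPS = 1e-7


@dataclass(frozen=True)
class LossValue:
    """A binary cross-entropy value (per-pixel mean) and the pixel count N."""

    J: float
    N: int

    @property
    def total(self) -> float:
        """The summed form of the objective, J * N."""
        return self.J * self.N


@dataclass
class TrainConfig:
    """Everything a training run needs, serializable into the run config."""

    n_train_mosaics: int = 100_000
    image_size: tuple[int, int] = (256, 256)
    batch_size: int = 8
    epochs: int = 10
    learning_rate: float = 1e-3
    beta_1: float = 0.9
    beta_2: float = 0.999
    master_seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_train_mosaics < 1 or self.batch_size < 1 or self.epochs < 0:
            raise InputError("counts must be positive (epochs may be 0)")
        if self.image_size[0] % 8 or self.image_size[1] % 8:
            raise InputError(f"image_size {self.image_size} must be divisible by 8")


def bce_loss(targets: np.ndarray, probs: np.ndarray) -> LossValue:
    """Mean binary cross-entropy between binary targets and probabilities."""
    targets = np.asarray(targets, dtype=np.float32)
    probs = np.asarray(probs, dtype=np.float32)
    if targets.shape != probs.shape:
        raise InputError(
            f"target shape {targets.shape} != probability shape {probs.shape}"
        )
    y = np.clip(probs, _EPS, 1.0 - _EPS)
    j = -np.mean(targets * np.log(y) + (1.0 - targets) * np.log1p(-y))
    return LossValue(J=float(j), N=targets.size)


def _resolve_training_arrays(
    data: DatasetManifest | Sequence[MosaicSample],
    root: str | Path | None,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, DatasetManifest):
        if len(data) == 0:
            raise InputError("empty manifest")
        if root is None:
            raise InputError("a manifest needs its dataset root directory")
        return load_manifest_arrays(data, root)
    samples = list(data)
    if not samples:
        raise InputError("no training samples")
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.target.mask for s in samples]).astype(np.float32)
    return images, masks


def fit_arrays(
    model: BoundaryNet,
    images: np.ndarray,
    masks: np.ndarray,
    cfg: TrainConfig,
    log_path: str | Path | None = None,
) -> list[float]:
    """Adam/BCE fitting loop on in-memory arrays; returns per-epoch mean loss.

    Masks must be binary {0, 1}; checkpoints are written per epoch when
    ``cfg.checkpoint_dir`` is set, and a CSV loss log when ``log_path`` is.
    """
    images = np.ascontiguousarray(images, dtype=np.float32)
    masks = np.ascontiguousarray(masks, dtype=np.float32)
    if images.shape[:3] != masks.shape:
        raise InputError(
            f"image batch {images.shape} inconsistent with mask batch {masks.shape}"
        )
    if not np.isin(masks, (0.0, 1.0)).all():
        raise InputError("masks must be binary {0, 1}")
    n = images.shape[0]
    opt = model.make_optimizer(cfg.learning_rate, cfg.beta_1, cfg.beta_2)
    rng = np.random.default_rng(cfg.master_seed)
    history: list[float] = []
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, tb = images[idx], masks[idx]
            probs = model.forward(xb, training=True)
            losses.append(bce_loss(tb, probs).J)
            weights.append(len(idx))
            model.backward((np.clip(probs, _EPS, 1 - _EPS) - tb) / tb.size)
            opt.step()
        history.append(float(np.average(losses, weights=weights)))
        if ckpt_dir:
            model.save(ckpt_dir / f"epoch_{epoch + 1:03d}.npz")
    if log_path is not None:
        with Path(log_path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "loss"])
            for i, loss in enumerate(history, start=1):
                writer.writerow([i, f"{loss:.6f}"])
    return history


def train(
    model: BoundaryNet,
    data: DatasetManifest | Sequence[MosaicSample],
    cfg: TrainConfig,
    root: str | Path | None = None,
    log_path: str | Path | None = None,
) -> tuple[BoundaryNet, list[float]]:
    """Train on a dataset manifest (or in-memory samples); thin wrapper over
    :func:`fit_arrays`.  Returns the model and the per-epoch loss history."""
    images, masks = _resolve_training_arrays(data, root)
    history = fit_arrays(model, images, masks, cfg, log_path=log_path)
    return model, history
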