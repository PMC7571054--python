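"""Edge-map evaluation: precision/recall, F-measure, Pratt Figure of Merit.

Border detection is a heavily imbalanced problem (border pixels are a small
fraction of each mosaic), so quality is summarized with precision--recall
based metrics rather than accuracy:

* precision = TP / (TP + FP), recall = TP / (TP + FN) over border pixels;
* F-measure = 2 * precision * recall / (precision + recall), their harmonic
  mean;
* the Pratt Figure of Merit

      R = 1 / max(I_I, I_A) * sum_{i=1}^{I_A} 1 / (1 + a d_i^2),

  where I_I and I_A count ideal (ground-truth) and actual (predicted) edge
  pixels, d_i is the Euclidean distance from predicted edge pixel i to the
  nearest ideal edge pixel, and a is a scaling constant, conventionally 1/9.
  R penalizes missed, displaced and spurious edge points and equals 1 for a
  perfect edge map.

A test-set report sweeps a probability-threshold grid, macro-averages the
per-image metrics at each threshold, and summarizes with the area under the
mean precision--recall curve, the maximum mean F-measure and the maximum mean
Pratt FOM.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError
from .mosaics import BorderMask

DEFAULT_THRESHOLD = 0.5  # the 50% convention used when a single map is reported


@dataclass(frozen=True)
class ThresholdMetrics:
    threshold: float
    precision: float
    recall: float
    f_measure: float


@dataclass(frozen=True)
class PrattConfig:
    """Scaling constant of the Figure of Merit distance penalty."""

    a: float = 1.0 / 9.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ConfigurationError(f"scaling constant a must be > 0, got {self.a}")


@dataclass
class EvalReport:
    """Per-threshold mean curves and the three summary scalars of a report row."""

    thresholds: np.ndarray
    mean_precision: np.ndarray
    mean_recall: np.ndarray
    mean_f: np.ndarray
    mean_fom: np.ndarray
    auc_pr: float
    max_mean_f: float
    max_mean_fom: float
    n_images: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "auc_pr": self.auc_pr,
                "max_mean_f": self.max_mean_f,
                "max_mean_fom": self.max_mean_fom,
                "n_images": self.n_images,
            },
            indent=2,
        ))

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["threshold", "precision", "recall", "f_measure", "fom"])
            for row in zip(self.thresholds, self.mean_precision, self.mean_recall,
                           self.mean_f, self.mean_fom):
                writer.writerow([f"{v:.6f}" for v in row])

    def plot_pr(self, path: str | Path) -> None:
        """Optional PNG of the mean precision--recall curve."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(self.mean_recall, self.mean_precision)
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_xlim(0, 1.02)
        ax.set_ylim(0, 1.02)
        ax.set_title(f"AUC = {self.auc_pr:.3f} (n = {self.n_images})")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _as_binary(arr: np.ndarray | BorderMask) -> np.ndarray:
    if isinstance(arr, BorderMask):
        return arr.mask.astype(bool)
    return np.asarray(arr).astype(bool)


def threshold_map(probs: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary edge map: pixel is edge iff its probability >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in [0, 1], got {threshold}")
    return (np.asarray(probs) >= threshold).astype(np.uint8)


def precision_recall(
    pred: np.ndarray, truth: np.ndarray | BorderMask
) -> tuple[float, float]:
    """Precision and recall of a binary edge map against the ground truth.

    Degenerate conventions: precision is 1 when nothing is predicted, recall
    is 1 when the truth contains no border pixels.
    """
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise InputError(f"prediction shape {p.shape} != truth shape {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return precision, recall


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def pratt_fom(
    pred: np.ndarray,
    truth: np.ndarray | BorderMask,
    cfg: PrattConfig = PrattConfig(),
) -> float:
    """Pratt Figure of Merit of a predicted edge map against the ideal one.

    The displacement d of each predicted edge pixel is its Euclidean distance
    to the nearest ideal edge pixel, computed with a distance transform.
    Conventions: 1 when both maps are empty, 0 when exactly one is.
    """
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise InputError(f"prediction shape {p.shape} != truth shape {t.shape}")
    n_ideal = int(np.count_nonzero(t))
    n_actual = int(np.count_nonzero(p))
    if n_ideal == 0 and n_actual == 0:
        return 1.0
    if n_ideal == 0 or n_actual == 0:
        return 0.0
    d = ndimage.distance_transform_edt(~t)
    contrib = 1.0 / (1.0 + cfg.a * d[p] ** 2)
    return float(contrib.sum() / max(n_ideal, n_actual))


def _image_metrics(
    probs: np.ndarray,
    truth: np.ndarray,
    thresholds: np.ndarray,
    cfg: PrattConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-threshold (precision, recall, F, FOM) for one probability map."""
    nt = len(thresholds)
    prec = np.empty(nt)
    rec = np.empty(nt)
    f = np.empty(nt)
    fom = np.empty(nt)
    t = _as_binary(truth)
    dist = None
    n_ideal = int(np.count_nonzero(t))
    if n_ideal:
        dist = ndimage.distance_transform_edt(~t)
    for i, thr in enumerate(thresholds):
        p = np.asarray(probs) >= thr
        prec[i], rec[i] = precision_recall(p, t)
        f[i] = f_measure(prec[i], rec[i])
        n_actual = int(np.count_nonzero(p))
        if n_ideal == 0 and n_actual == 0:
            fom[i] = 1.0
        elif n_ideal == 0 or n_actual == 0:
            fom[i] = 0.0
        else:
            contrib = 1.0 / (1.0 + cfg.a * dist[p] ** 2)
            fom[i] = contrib.sum() / max(n_ideal, n_actual)
    return prec, rec, f, fom


def auc_precision_recall(mean_recall: np.ndarray, mean_precision: np.ndarray) -> float:
    """Trapezoidal area under the mean PR curve.

    The curve is traversed as the threshold sweeps from high to low, i.e. by
    non-decreasing recall; vertical segments (recall ties) contribute nothing,
    so the path integral is well defined even for saturated predictors.
    ``mean_recall``/``mean_precision`` are indexed by increasing threshold.
    """
    r = np.asarray(mean_recall)[::-1]
    p = np.asarray(mean_precision)[::-1]
    return float(np.trapezoid(p, r))


def evaluate_testset(
    model,
    samples: Sequence,
    thresholds: np.ndarray | None = None,
    cfg: PrattConfig = PrattConfig(),
    average: str = "macro",
    f_mode: str = "mean_of_f",
) -> EvalReport:
    """Evaluate a model (or precomputed probability maps) over a test set.

    Parameters
    ----------
    model
        Anything with ``predict(image) -> probability map``, or None when
        ``samples`` already pairs probability maps with truths.
    samples
        Sequence of objects with ``image`` and ``target`` attributes
        (e.g. MosaicSample), or of ``(prob_map, truth)`` pairs when model is
        None.
    thresholds
        Strictly increasing grid in [0, 1]; default 101 evenly spaced values.
    average
        "macro" (default): average per-image metrics at each threshold.
        "micro": pool TP/FP/FN over images before computing the metrics
        (FOM is always macro-averaged, being inherently per-image).
    f_mode
        "mean_of_f" (default): the reported F curve is the mean of per-image
        F values.  "f_of_means": F of the mean precision and recall.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or np.any(np.diff(thresholds) <= 0):
        raise ConfigurationError("thresholds must be strictly increasing")
    if thresholds.min() < 0 or thresholds.max() > 1:
        raise ConfigurationError("thresholds must lie in [0, 1]")
    if average not in ("macro", "micro"):
        raise ConfigurationError(f"average must be 'macro' or 'micro', got {average!r}")
    if f_mode not in ("mean_of_f", "f_of_means"):
        raise ConfigurationError(f"unknown f_mode {f_mode!r}")
    samples = list(samples)
    if not samples:
        raise InputError("empty test set")

    all_prec, all_rec, all_f, all_fom = [], [], [], []
    confusion = np.zeros((len(thresholds), 3))  # TP, FP, FN pooled (micro)
    for item in samples:
        if model is None:
            probs, truth = item
        else:
            probs, truth = model.predict(item.image), item.target
        prec, rec, f, fom = _image_metrics(probs, truth, thresholds, cfg)
        all_prec.append(prec)
        all_rec.append(rec)
        all_f.append(f)
        all_fom.append(fom)
        if average == "micro":
            t = _as_binary(truth)
            for i, thr in enumerate(thresholds):
                p = np.asarray(probs) >= thr
                confusion[i] += (
                    np.count_nonzero(p & t),
                    np.count_nonzero(p & ~t),
                    np.count_nonzero(~p & t),
                )

    mean_fom = np.mean(all_fom, axis=0)
    if average == "macro":
        mean_prec = np.mean(all_prec, axis=0)
        mean_rec = np.mean(all_rec, axis=0)
    else:
        tp, fp, fn = confusion.T
        mean_prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 1.0)
        mean_rec = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 1.0)
    if f_mode == "mean_of_f" and average == "macro":
        mean_f = np.mean(all_f, axis=0)
    else:
        mean_f = np.array([f_measure(p, r) for p, r in zip(mean_prec, mean_rec)])

    return EvalReport(
        thresholds=thresholds,
        mean_precision=mean_prec,
        mean_recall=mean_rec,
        mean_f=mean_f,
        mean_fom=mean_fom,
        auc_pr=auc_precision_recall(mean_rec, mean_prec),
        max_mean_f=float(mean_f.max()),
        max_mean_fom=float(mean_fom.max()),
        n_images=len(samples),
    )
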