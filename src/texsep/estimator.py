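"""scikit-learn style estimator wrapping the boundary network and its trainer."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .errors import InputError
from .network import BoundaryNet
from .train import TrainConfig, fit_arrays


class TextureBoundarySegmenter(BaseEstimator):
    """Pixel-wise texture-boundary classifier with a scikit-learn interface.

    Wraps the encoder--decoder boundary network: ``fit`` trains it with Adam
    on the binary cross-entropy objective, ``predict_proba`` returns per-pixel
    boundary probability maps and ``predict`` thresholds them (default 50%).

    Parameters
    ----------
    epochs : int
        Number of passes over the training mosaics.
    batch_size : int
        Mosaics per Adam update.
    learning_rate, beta_1, beta_2 : float
        Adam hyper-parameters (defaults are the standard ones).
    threshold : float
        Probability cut used by :meth:`predict`.
    random_state : int
        Seeds weight initialization and batch shuffling.

    Attributes
    ----------
    model_ : BoundaryNet
        The fitted network.
    loss_history_ : list of float
        Mean training loss per epoch.
    n_features_in_ : int
        Pixels per training image (H * W * 3).

    Examples
    --------
    >>> seg = TextureBoundarySegmenter(epochs=2, random_state=0)
    >>> seg.fit(images, masks)            # images (n, H, W, 3), masks (n, H, W)
    >>> prob_maps = seg.predict_proba(images[:4])
    >>> edge_maps = seg.predict(images[:4])
    """

    def __init__(
        self,
        epochs: int = 10,
        batch_size: int = 8,
        learning_rate: float = 1e-3,
        beta_1: float = 0.9,
        beta_2: float = 0.999,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta_1 = beta_1
        self.beta_2 = beta_2
        self.threshold = threshold
        self.random_state = random_state

    @staticmethod
    def _validate_images(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[3] != 3:
            raise InputError(f"X must be (n, H, W, 3), got shape {X.shape}")
        if X.shape[1] % 8 or X.shape[2] % 8:
            raise InputError("image sides must be divisible by 8")
        if X.min() < 0.0 or X.max() > 1.0:
            raise InputError("image values must lie in [0, 1]")
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TextureBoundarySegmenter":
        """Train on mosaics ``X`` (n, H, W, 3) and binary masks ``y`` (n, H, W)."""
        X = self._validate_images(X)
        y = np.asarray(y, dtype=np.float32)
        if y.shape != X.shape[:3]:
            raise InputError(f"y must be (n, H, W) matching X, got {y.shape}")
        cfg = TrainConfig(
            n_train_mosaics=X.shape[0],
            image_size=(X.shape[1], X.shape[2]),
            batch_size=self.batch_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            beta_1=self.beta_1,
            beta_2=self.beta_2,
            master_seed=self.random_state,
        )
        self.model_ = BoundaryNet(input_size=cfg.image_size, seed=self.random_state)
        self.loss_history_ = fit_arrays(self.model_, X, y, cfg)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Boundary probability maps, shape (n, H, W), values in (0, 1)."""
        self._check_fitted()
        X = self._validate_images(X)
        return self.model_.predict_batch(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary edge maps: probability >= ``threshold`` (default 0.5)."""
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean F-measure of the thresholded maps against binary masks ``y``."""
        from .evaluate import f_measure, precision_recall

        preds = self.predict(X)
        y = np.asarray(y)
        scores = [
            f_measure(*precision_recall(p, t)) for p, t in zip(preds, y)
        ]
        return float(np.mean(scores))

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise InputError("this TextureBoundarySegmenter instance is not fitted yet")
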