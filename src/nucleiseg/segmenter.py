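"""Scikit-learn style estimator wrapping the segmentation network.

``UNetSegmenter`` follows the sklearn estimator contract — constructor
stores hyperparameters verbatim, ``fit(X, y)`` learns and sets trailing-
underscore attributes, ``get_params``/``set_params`` make it clonable and
pipeline/grid-search compatible.  ``X`` is a batch of grayscale images
``(n, H, W)`` with values in [0, 1]; ``y`` holds the binary foreground
masks.  Training minimizes the hybrid BCE + soft-Dice loss with Adam.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator

from . import pipeline
from .config import ArchConfig, TrainConfig
from .metrics import dice_coefficient, hybrid_loss
from .model import NetworkHandle, assemble_variant, count_parameters
from .engine import Adam


class TrainingDiverged(RuntimeError):
    pass


class UNetSegmenter(BaseEstimator):
    """Binary nuclei segmenter around the lightweight attention U-Net.

    Parameters
    ----------
    variant : which architecture to build ("full", "no_depthwise",
        "no_residual", "no_attention", "no_reduction", "baseline_unet").
    alpha : BCE weight of the hybrid loss (1 - alpha weighs the Dice term).
    learning_rate, batch_size, epochs : Adam loop hyperparameters.
    augment : apply seeded flips/rotations/jitter to each training sample.
    threshold : probability cut for ``predict``.
    patience : epochs without monitored-Dice improvement before stopping.
    early_stop_dice : optional training-Dice level at which to stop early.
    arch_config : explicit ``ArchConfig``; by default one is derived from the
        data (input_size taken from X) with ``seed``.

    Attributes (after ``fit``)
    --------------------------
    net_ : the built ``NetworkHandle`` with trained weights.
    history_ : per-epoch train/validation loss and Dice curves.
    n_parameters_ : exact trainable-parameter count.
    """

    def __init__(self, variant: str = "full", alpha: float = 0.5,
                 learning_rate: float = 1e-3, batch_size: int = 8,
                 epochs: int = 50, seed: int = 0, augment: bool = False,
                 threshold: float = 0.5, patience: int = 20,
                 early_stop_dice: float | None = None,
                 arch_config: ArchConfig | None = None):
        self.variant = variant
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.augment = augment
        self.threshold = threshold
        self.patience = patience
        self.early_stop_dice = early_stop_dice
        self.arch_config = arch_config

    # -- helpers ----------------------------------------------------------
    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_samples, H, W), got {X.shape}")
        if y is None:
            return X, None
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError(f"y shape {y.shape} must match X {X.shape}")
        vals = np.unique(y)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("y must be binary masks")
        return X, y.astype(np.float32)

    def _build(self, input_size: int) -> NetworkHandle:
        cfg = self.arch_config or ArchConfig(input_size=input_size, seed=self.seed)
        if cfg.input_size != input_size:
            cfg = dataclasses.replace(cfg, input_size=input_size)
        return assemble_variant(cfg, self.variant)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y, sample_weight=None, validation=None):
        """Train on images X and binary masks y.

        ``validation`` is an optional ``(X_val, y_val)`` pair monitored for
        checkpointing and early stopping; without it the training Dice is
        monitored instead.
        """
        X, y = self._validate_xy(X, y)
        n, h, w = X.shape
        if h != w:
            raise ValueError("images must be square")
        if sample_weight is None:
            sw = np.ones(n, dtype=np.float64)
        else:
            sw = np.asarray(sample_weight, dtype=np.float64)
            if sw.shape != (n,):
                raise ValueError("sample_weight must have one entry per sample")
        Xval = yval = None
        if validation is not None:
            Xval, yval = self._validate_xy(*validation)

        handle = self._build(h)
        net = handle.net
        opt = Adam(net.params(), lr=self.learning_rate)
        rng = np.random.default_rng(self.seed)

        history = {"train_loss": [], "train_dice": [], "val_loss": [], "val_dice": []}
        best_state, best_metric, stale = None, -np.inf, 0
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            inter = psum = tsum = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                if self.augment:
                    xb = np.empty((len(idx), h, w), dtype=np.float32)
                    yb = np.empty((len(idx), h, w), dtype=np.float32)
                    for k, i in enumerate(idx):
                        xi, yi = pipeline.augment(X[i], y[i], rng, elastic=False)
                        xb[k], yb[k] = xi, yi
                else:
                    xb, yb = X[idx], y[idx]
                probs = net.forward(xb[:, None], training=True)
                target = yb[:, None]
                loss, grad = hybrid_loss(probs, target, alpha=self.alpha,
                                         sample_weight=sw[idx], return_grad=True)
                if not np.isfinite(loss):
                    raise TrainingDiverged(
                        f"non-finite loss at epoch {epoch}; lower the learning "
                        "rate or check input normalization")
                net.zero_grad()
                net.backward(grad.astype(probs.dtype))
                opt.step()
                epoch_losses.append(loss)
                pb = probs >= self.threshold
                inter += float((pb & (target > 0.5)).sum())
                psum += float(pb.sum())
                tsum += float(target.sum())
            train_dice = 2.0 * inter / (psum + tsum) if psum + tsum else 1.0
            history["train_loss"].append(float(np.mean(epoch_losses)))
            history["train_dice"].append(train_dice)

            if Xval is not None:
                vprobs = net.forward(Xval[:, None], training=False)
                vloss = hybrid_loss(vprobs, yval[:, None], alpha=self.alpha)
                vpred = vprobs >= self.threshold
                vd_num = 2.0 * float((vpred & (yval[:, None] > 0.5)).sum())
                vd_den = float(vpred.sum() + yval.sum())
                val_dice = vd_num / vd_den if vd_den else 1.0
                history["val_loss"].append(float(vloss))
                history["val_dice"].append(val_dice)
                monitored = val_dice
            else:
                monitored = train_dice

            if monitored > best_metric:
                best_metric, stale = monitored, 0
                best_state = {k: v.copy() for k, v in net.state_dict().items()}
            else:
                stale += 1
            if self.early_stop_dice is not None and train_dice >= self.early_stop_dice:
                break
            if stale > self.patience:
                break

        if best_state is not None:
            net.load_state_dict(best_state)
        self.net_ = handle
        self.history_ = history
        self.n_parameters_ = count_parameters(handle)
        self.n_epochs_run_ = len(history["train_loss"])
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel foreground probabilities, shape (n, H, W)."""
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        X, _ = self._validate_xy(X)
        out = np.empty(X.shape, dtype=np.float32)
        for start in range(0, X.shape[0], max(1, self.batch_size)):
            xb = X[start:start + self.batch_size]
            out[start:start + xb.shape[0]] = self.net_.net.forward(
                xb[:, None], training=False)[:, 0]
        return out

    def predict(self, X) -> np.ndarray:
        """Binary masks at the configured threshold, shape (n, H, W)."""
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-image Dice coefficient."""
        X, y = self._validate_xy(X, y)
        preds = self.predict(X)
        return float(np.mean([dice_coefficient(p, t) for p, t in zip(preds, y)]))

    @classmethod
    def from_train_config(cls, config: TrainConfig,
                          variant: str = "full") -> "UNetSegmenter":
        return cls(variant=variant, alpha=config.alpha,
                   learning_rate=config.learning_rate,
                   batch_size=config.batch_size, epochs=config.epochs,
                   seed=config.seed, augment=config.augment,
                   patience=config.patience, arch_config=config.arch)
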