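"""Iris segmentation network.

The segmentor reuses the synthesis generator's U-Net with the input
channel set to one (grayscale image) and a per-pixel channel softmax
head, so each pixel carries a categorical distribution over the class
set (binary iris / non-iris by default; a 3-class background /
periocular / iris mode is available).

The training loss is the fully convolutional network loss

    L(P, Q) = - sum_i sum_j sum_k Q_k(i,j) log P_k(i,j)

— cross-entropy summed over all pixel positions (not averaged), where
P is the predicted distribution and Q the one-hot label map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .nn import Adam, UNet

_LOG_EPS = 1e-12


@dataclass(frozen=True)
class SegConfig:
    """Optimization recipe: Adam, lr 1e-5, beta1 0.5, beta2 0.99,
    batch 64, 10 epochs, Gaussian init."""

    n_classes: int = 2
    learning_rate: float = 1e-5
    beta1: float = 0.5
    beta2: float = 0.99
    batch_size: int = 64
    epochs: int = 10
    init_std: float = 0.02

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(…, H, W) integer labels -> (…, n_classes, H, W) one-hot float32."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels out of range")
    eye = np.eye(n_classes, dtype=np.float32)
    oh = eye[labels]  # (..., H, W, k)
    return np.moveaxis(oh, -1, -3)


def fcn_loss(P: np.ndarray, Q: np.ndarray) -> float:
    """Cross-entropy summed over every pixel position.

    ``P`` and ``Q`` are (k, H, W) maps (or batches (b, k, H, W), in
    which case the per-image sums are averaged over the batch).
    P rows must be per-pixel distributions, Q one-hot labels.
    """
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError("P and Q shapes differ")
    total = -(Q * np.log(np.clip(P, _LOG_EPS, None))).sum(axis=tuple(range(P.ndim - 3, P.ndim)))
    return float(np.mean(total))


class IrisSegmenter(BaseEstimator):
    """U-Net pixel classifier for iris segmentation.

    Parameters mirror :class:`SegConfig` plus the architecture knobs
    shared with the synthesis generator (``depth``, ``base_width``,
    ``dropout_layers``).

    Attributes
    ----------
    net_ : UNet
        The trained network (1 input channel, ``n_classes`` softmax outputs).
    history_ : pandas.DataFrame
        Per-epoch mean training loss (and validation loss when given).
    classes_ : ndarray
        ``[0, ..., n_classes - 1]``.
    """

    def __init__(
        self,
        n_classes: int = 2,
        depth: int = 8,
        base_width: int = 64,
        learning_rate: float = 1e-5,
        beta1: float = 0.5,
        beta2: float = 0.99,
        batch_size: int = 64,
        epochs: int = 10,
        dropout_layers: int = 5,
        init_std: float = 0.02,
        random_state: int = 0,
    ) -> None:
        self.n_classes = n_classes
        self.depth = depth
        self.base_width = base_width
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.epochs = epochs
        self.dropout_layers = dropout_layers
        self.init_std = init_std
        self.random_state = random_state

    def _as_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[:, None]
        if X.ndim != 4 or X.shape[1] != 1:
            raise ValueError("images must be (n, H, W) or (n, 1, H, W) grayscale")
        return X

    def _as_Q(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        if y.ndim == 3:  # integer label maps
            return one_hot(y.astype(np.int64), self.n_classes)
        if y.ndim == 4 and y.shape[1] == self.n_classes:
            return y.astype(np.float32)
        raise ValueError("labels must be (n, H, W) integers or (n, k, H, W) one-hot")

    def fit(self, X: np.ndarray, y: np.ndarray, validation=None) -> "IrisSegmenter":
        """Mini-batch Adam training with the summed cross-entropy loss.

        ``validation``: optional (X_val, y_val) pair; its loss is logged
        per epoch (the network stays in eval mode for it).
        """
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        X = self._as_X(X)
        Q = self._as_Q(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != len(Q) or X.shape[2:] != Q.shape[2:]:
            raise ValueError("images and labels disagree in count or resolution")
        rng = np.random.default_rng(self.random_state)
        net = UNet(1, self.n_classes, depth=self.depth, base_width=self.base_width,
                   dropout_layers=self.dropout_layers, final="softmax", rng=rng)
        opt = Adam(net.parameters(), self.learning_rate, (self.beta1, self.beta2))
        n = len(X)
        bs = min(self.batch_size, n)
        records = []
        for _ in range(int(self.epochs)):
            order = rng.permutation(n)
            losses = []
            net.train()
            for start in range(0, n - bs + 1, bs):
                idx = order[start : start + bs]
                P = net.forward(X[idx])
                Qb = Q[idx]
                losses.append(fcn_loss(P, Qb))
                grad = -(Qb / np.clip(P, 1e-7, None)) / len(idx)
                net.zero_grad()
                net.backward(grad.astype(np.float32))
                opt.step()
            rec = {"train_loss": float(np.mean(losses))}
            if validation is not None:
                net.eval()
                Xv = self._as_X(validation[0])
                Qv = self._as_Q(validation[1])
                rec["val_loss"] = fcn_loss(net.forward(Xv), Qv)
            records.append(rec)
        net.eval()
        self.net_ = net
        self.history_ = pd.DataFrame(records)
        self.classes_ = np.arange(self.n_classes)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-pixel class distributions, (n, k, H, W)."""
        self._check_fitted()
        X = self._as_X(X)
        out = []
        for start in range(0, len(X), 32):
            out.append(self.net_.forward(X[start : start + 32]))
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax label maps, (n, H, W); ties break toward the lower class."""
        return np.argmax(self.predict_proba(X), axis=1)

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("segmenter is not fitted")

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: constructor params and network weights."""
        import json

        self._check_fitted()
        arrays = {f"w{i}": p.data for i, p in enumerate(self.net_.parameters())}
        meta = json.dumps({"params": self.get_params()})
        np.savez(path, meta=np.array(meta), **arrays)

    @classmethod
    def load(cls, path) -> "IrisSegmenter":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            model = cls(**meta["params"])
            rng = np.random.default_rng(model.random_state)
            net = UNet(1, model.n_classes, depth=model.depth, base_width=model.base_width,
                       dropout_layers=model.dropout_layers, final="softmax", rng=rng)
            for i, p in enumerate(net.parameters()):
                p.data[...] = data[f"w{i}"]
        net.eval()
        model.net_ = net
        model.history_ = pd.DataFrame()
        model.classes_ = np.arange(model.n_classes)
        return model


# -- thin functional wrappers -------------------------------------------


def seg_forward(model: IrisSegmenter, image: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities for a single image, (k, H, W)."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("expected a single-channel (H, W) image")
    return model.predict_proba(image[None])[0]


def predict_mask(model: IrisSegmenter, image: np.ndarray) -> np.ndarray:
    """Binary (or k-ary) label map for one image."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("expected a single-channel (H, W) image")
    return model.predict(image[None])[0]


def train_segmentation(
    images: np.ndarray,
    labels: np.ndarray,
    config: SegConfig | None = None,
    depth: int = 8,
    base_width: int = 64,
    random_state: int = 0,
    validation=None,
) -> IrisSegmenter:
    config = config if config is not None else SegConfig()
    config.validate()
    model = IrisSegmenter(
        n_classes=config.n_classes,
        depth=depth,
        base_width=base_width,
        learning_rate=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        batch_size=config.batch_size,
        epochs=config.epochs,
        init_std=config.init_std,
        random_state=random_state,
    )
    return model.fit(images, labels, validation=validation)
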