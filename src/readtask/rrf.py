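"""Reading-fluency-related features (RRF) via frozen-backbone transfer learning.

A pretrained convolutional backbone is frozen and used purely as a feature
extractor; only a freshly initialized binary fully-connected head is
trained (mini-batch 10, 140 epochs, learning rate 1e-4 by default).  Each
fluency image (time-domain map, 3-D spectrogram) passes through its own
head, and the two pre-softmax outputs per head concatenate — map first —
into the 4-element RRF vector.

Backbones are pluggable through :class:`BackboneSpec`.  The default
``"tiny-random"`` backbone is a small seeded random-convolution network:
its filters are drawn once from a fixed seed and never updated, which
preserves every contract of the transfer-learning path (frozen
convolutions, deterministic features, trainable head) without requiring
pretrained weights.  Any object with ``features(image) -> 1-D array`` and
``checksum() -> float`` can be registered in its place.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FluencyImage

__all__ = [
    "BackboneSpec",
    "TrainConfig",
    "TinyConvBackbone",
    "build_backbone",
    "register_backbone",
    "RRFModel",
    "train_head",
    "extract_rrf",
    "RRFFoldExtractor",
]


@dataclass(frozen=True)
class BackboneSpec:
    """Which frozen convolutional backbone to use and at what input size."""

    name: str = "tiny-random"
    input_side: int = 224
    frozen: bool = True

    def __post_init__(self) -> None:
        if not self.frozen:
            raise ValueError("convolutional layers are always frozen in this pipeline")
        if self.input_side < 8:
            raise ValueError("input_side too small")


@dataclass(frozen=True)
class TrainConfig:
    """Head-training hyperparameters (defaults follow the published recipe)."""

    batch_size: int = 10
    epochs: int = 140
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs and learning_rate must be positive")


class TinyConvBackbone:
    """Seeded random two-layer convolutional feature extractor (frozen).

    Filters are drawn once from ``weight_seed`` and never modified.  The
    input image is mean-pooled to 56x56, passed through two 3x3
    convolution + ReLU stages with an intervening 2x2 max pool, and reduced
    to a per-channel mean + max global pooling, giving a 32-dimensional
    feature vector.
    """

    name = "tiny-random"

    def __init__(self, input_side: int = 224, weight_seed: int = 1234) -> None:
        self.input_side = input_side
        rng = np.random.default_rng(weight_seed)
        self.conv1 = rng.normal(0.0, np.sqrt(2.0 / (3 * 9)), size=(8, 3, 3, 3))
        self.conv2 = rng.normal(0.0, np.sqrt(2.0 / (8 * 9)), size=(16, 8, 3, 3))

    # -- frozen-parameter accounting -------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [self.conv1, self.conv2]

    def checksum(self) -> float:
        return float(sum(np.abs(p).sum() for p in self.parameters()))

    # -- forward ----------------------------------------------------------
    @staticmethod
    def _pool_mean(x: np.ndarray, k: int) -> np.ndarray:
        h, w = x.shape[:2]
        hk, wk = h // k, w // k
        x = x[: hk * k, : wk * k]
        return x.reshape(hk, k, wk, k, *x.shape[2:]).mean(axis=(1, 3))

    @staticmethod
    def _conv(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """Valid 3x3 convolution: x (H, W, Cin), weights (Cout, Cin, 3, 3)."""
        win = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(0, 1))
        # win: (H-2, W-2, Cin, 3, 3)
        return np.einsum("hwcij,ocij->hwo", win, weights)

    @staticmethod
    def _maxpool(x: np.ndarray, k: int = 2) -> np.ndarray:
        h, w, c = x.shape
        hk, wk = h // k, w // k
        x = x[: hk * k, : wk * k]
        return x.reshape(hk, k, wk, k, c).max(axis=(1, 3))

    def features(self, image: np.ndarray | FluencyImage) -> np.ndarray:
        if isinstance(image, FluencyImage):
            image = image.pixels
        x = np.asarray(image, dtype=float)
        if x.ndim != 3 or x.shape[2] != 3:
            raise ValueError("backbone expects an H x W x 3 image")
        x = x / 255.0 - 0.5
        k = max(1, x.shape[0] // 56)
        x = self._pool_mean(x, k)
        x = np.maximum(self._conv(x, self.conv1), 0.0)
        x = self._maxpool(x, 2)
        x = np.maximum(self._conv(x, self.conv2), 0.0)
        return np.concatenate([x.mean(axis=(0, 1)), x.max(axis=(0, 1))])


def _resnet101_unavailable(spec: BackboneSpec):
    raise RuntimeError(
        "the 'resnet101' backbone requires a pretrained residual network; "
        "register one with register_backbone('resnet101', factory) or use the "
        "default 'tiny-random' backbone"
    )


_BACKBONES = {
    "tiny-random": lambda spec: TinyConvBackbone(input_side=spec.input_side),
    "resnet101": _resnet101_unavailable,
}


def register_backbone(name: str, factory) -> None:
    """Register a backbone factory: ``factory(spec) -> object with .features``."""
    _BACKBONES[name] = factory


def build_backbone(spec: BackboneSpec):
    try:
        factory = _BACKBONES[spec.name]
    except KeyError:
        raise KeyError(
            f"unknown backbone {spec.name!r}; registered: {sorted(_BACKBONES)}"
        ) from None
    return factory(spec)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class RRFModel:
    """Frozen backbone + trained binary head + training history."""

    backbone: object
    feat_mean: np.ndarray
    feat_std: np.ndarray
    weights: np.ndarray  # (d, 2)
    bias: np.ndarray  # (2,)
    history: pd.DataFrame = field(repr=False, default=None)
    trained: bool = False

    def _standardize(self, feats: np.ndarray) -> np.ndarray:
        return (feats - self.feat_mean) / self.feat_std

    def logits(self, image: np.ndarray | FluencyImage) -> np.ndarray:
        """Pre-softmax outputs of the binary head for one image (length 2)."""
        if not self.trained:
            raise RuntimeError("head has not been trained")
        f = self._standardize(np.asarray(self.backbone.features(image)))
        return f @ self.weights + self.bias

    def probabilities(self, image: np.ndarray | FluencyImage) -> np.ndarray:
        return _softmax(self.logits(image)[None, :])[0]


def _train_head_on_features(
    feats: np.ndarray, labels: np.ndarray, cfg: TrainConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Seeded mini-batch SGD on a softmax cross-entropy binary head."""
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("head training needs both classes present")
    if np.any(np.bincount(labels, minlength=2)[:2] < 1) or not np.all(np.isin(classes, [0, 1])):
        raise ValueError("labels must be binary {0, 1} with both classes present")

    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std[std < 1e-8] = 1.0
    x = (feats - mean) / std

    rng = np.random.default_rng(cfg.seed)
    d = x.shape[1]
    w = rng.normal(0.0, 0.01, size=(d, 2))
    b = np.zeros(2)
    onehot = np.eye(2)[labels]
    n = x.shape[0]
    hist = {"epoch": [], "loss": [], "accuracy": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = x[sel], onehot[sel]
            probs = _softmax(xb @ w + b)
            grad = probs - yb
            w -= cfg.learning_rate * xb.T @ grad / sel.size
            b -= cfg.learning_rate * grad.mean(axis=0)
        logits = x @ w + b
        probs = _softmax(logits)
        loss = -np.mean(np.log(np.maximum(probs[np.arange(n), labels], 1e-12)))
        acc = float(np.mean(np.argmax(logits, axis=1) == labels))
        hist["epoch"].append(epoch + 1)
        hist["loss"].append(float(loss))
        hist["accuracy"].append(acc)
    return w, b, mean, std, pd.DataFrame(hist)


def train_head(
    images: list[np.ndarray | FluencyImage],
    labels: np.ndarray,
    spec: BackboneSpec | None = None,
    cfg: TrainConfig | None = None,
    backbone: object | None = None,
) -> RRFModel:
    """Train the binary fully-connected head on frozen backbone features.

    Only the head's parameters change; the backbone is used read-only.
    Training is deterministic given ``cfg.seed``.  Raises on single-class
    input.
    """
    spec = spec or BackboneSpec()
    cfg = cfg or TrainConfig()
    if backbone is None:
        backbone = build_backbone(spec)
    feats = np.stack([np.asarray(backbone.features(img)) for img in images])
    w, b, mean, std, hist = _train_head_on_features(feats, np.asarray(labels), cfg)
    return RRFModel(
        backbone=backbone, feat_mean=mean, feat_std=std,
        weights=w, bias=b, history=hist, trained=True,
    )


def extract_rrf(
    map_img: np.ndarray | FluencyImage,
    spec_img: np.ndarray | FluencyImage,
    map_model: RRFModel,
    spec_model: RRFModel,
) -> np.ndarray:
    """The 4-element RRF vector: map-head logits then spectrogram-head logits."""
    out = np.concatenate([map_model.logits(map_img), spec_model.logits(spec_img)])
    if out.shape != (4,) or not np.all(np.isfinite(out)):
        raise RuntimeError("RRF vector must be 4 finite values")
    return out


class RRFFoldExtractor:
    """Per-fold RRF feature provider for cross-validation.

    Backbone features for every image are computed once (legitimate: the
    convolutional layers are frozen, so they are identical in every fold);
    the binary heads are retrained from scratch on each fold's training
    rows only, so no test-fold image ever influences the head that embeds
    it.
    """

    def __init__(
        self,
        map_images: list,
        spec_images: list,
        labels: np.ndarray,
        spec: BackboneSpec | None = None,
        cfg: TrainConfig | None = None,
    ) -> None:
        spec = spec or BackboneSpec()
        self.cfg = cfg or TrainConfig()
        self.backbone = build_backbone(spec)
        self.labels = np.asarray(labels).astype(int)
        self._map_feats = np.stack(
            [np.asarray(self.backbone.features(i)) for i in map_images]
        )
        self._spec_feats = np.stack(
            [np.asarray(self.backbone.features(i)) for i in spec_images]
        )

    def features_for_fold(self, train_idx: np.ndarray, fold_seed: int) -> np.ndarray:
        """(n_rows, 4) RRF features with heads trained on ``train_idx`` only."""
        cfg = TrainConfig(
            batch_size=self.cfg.batch_size,
            epochs=self.cfg.epochs,
            learning_rate=self.cfg.learning_rate,
            seed=fold_seed,
        )
        cols = []
        for feats in (self._map_feats, self._spec_feats):
            w, b, mean, std, _ = _train_head_on_features(
                feats[train_idx], self.labels[train_idx], cfg
            )
            cols.append((feats - mean) / std @ w + b)
        return np.hstack(cols)
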