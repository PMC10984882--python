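"""Classifier architecture and the two-stage transfer-learning protocol.

The network is: a learnable grayscale-to-RGB adapter (one Conv2D with three
3x3 filters, same padding) -> a backbone feature extractor -> global average
pooling -> dropout 0.5 -> a single-unit sigmoid head. Training proceeds in
two stages: stage 1 trains the added layers with the backbone feature
extractor frozen (the transfer-learning step); stage 2 fine-tunes with a
much lower learning rate, unfreezing the backbone fully, partially (last k
parameterized layers), or not at all. Both stages monitor validation
accuracy and stop after `patience` epochs without improvement, restoring
the best-epoch weights.

For a randomly initialized (non-pretrained) backbone there is no feature
extractor worth protecting, so stage 1 trains all layers by default; the
freeze behaviour can be forced either way via ``freeze_backbone_stage1``.

The built-in ``tiny-scratch`` backbone is a four-block CNN small enough to
train on one CPU core; named pretrained families can be plugged in through
``register_backbone`` without changes to the training protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .nn import (
    Adam,
    BatchNorm2D,
    Conv2D,
    Dense,
    Dropout,
    GlobalAvgPool,
    Layer,
    MaxPool2,
    ReLU,
    SequentialNet,
    bce_with_logits,
    sigmoid,
)


class ConfigurationError(ValueError):
    """Raised for unresolvable backbones or inconsistent model settings."""


@dataclass
class BackboneSpec:
    name: str = "tiny-scratch"
    input_size: tuple[int, int] = (64, 64)
    pretrained: bool = False
    unfreeze_mode: str = "all"  # head-only | all | last-k-layers
    k: int = 3

    def validate(self) -> None:
        if self.unfreeze_mode not in ("head-only", "all", "last-k-layers"):
            raise ConfigurationError(f"unknown unfreeze_mode {self.unfreeze_mode!r}")
        if self.unfreeze_mode == "last-k-layers" and self.k < 1:
            raise ConfigurationError("last-k-layers requires k >= 1")


@dataclass
class AugmentConfig:
    brightness_delta: float = 0.1  # multiplicative, +/- fraction
    zoom: float = 0.1  # +/- fraction around unity
    rotation: float = 360.0  # degrees; angles drawn uniformly from [0, rotation)


@dataclass
class TrainConfig:
    stage1_lr: float = 3e-3
    stage2_lr: float = 1e-5
    batch_size: int = 8
    patience: int = 4
    max_epochs: int = 100
    monitor: str = "val_accuracy"
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    dropout: float = 0.5
    threshold: float = 0.5
    seed: int = 0
    freeze_backbone_stage1: Optional[bool] = None  # None -> freeze iff backbone pretrained

    def validate(self) -> None:
        if not (0 < self.stage2_lr < self.stage1_lr):
            raise ConfigurationError("stage2_lr must be positive and below stage1_lr")
        if self.patience < 1 or self.max_epochs < 1:
            raise ConfigurationError("patience and max_epochs must be >= 1")


# ---------------------------------------------------------------------------
# Backbone registry

BackboneFactory = Callable[[BackboneSpec, np.random.Generator], tuple[list[Layer], int]]
_BACKBONES: dict[str, BackboneFactory] = {}


def register_backbone(name: str, factory: BackboneFactory) -> None:
    _BACKBONES[name] = factory


def _tiny_scratch(spec: BackboneSpec, rng: np.random.Generator) -> tuple[list[Layer], int]:
    h, w = spec.input_size
    if h % 8 or w % 8:
        raise ConfigurationError("tiny-scratch input size must be divisible by 8")
    layers: list[Layer] = [
        Conv2D(3, 8, rng=rng), BatchNorm2D(8), ReLU(), MaxPool2(),
        Conv2D(8, 12, rng=rng), BatchNorm2D(12), ReLU(), MaxPool2(),
        Conv2D(12, 16, rng=rng), BatchNorm2D(16), ReLU(), MaxPool2(),
        Conv2D(16, 16, rng=rng), BatchNorm2D(16), ReLU(),
    ]
    return layers, 16


register_backbone("tiny-scratch", _tiny_scratch)


def build_classifier(backbone: BackboneSpec, seed: int = 0) -> SequentialNet:
    """Assemble adapter -> backbone -> GAP -> dropout(0.5) -> sigmoid-unit head."""
    backbone.validate()
    if backbone.name not in _BACKBONES:
        raise ConfigurationError(
            f"unknown backbone {backbone.name!r}; registered: {sorted(_BACKBONES)}"
        )
    rng = np.random.default_rng(seed)
    adapter = Conv2D(1, 3, rng=rng)
    adapter.group = "adapter"
    body, feat_dim = _BACKBONES[backbone.name](backbone, rng)
    for layer in body:
        layer.group = "backbone"
    gap, drop, head = GlobalAvgPool(), Dropout(0.5), Dense(feat_dim, 1, rng=rng)
    for layer in (gap, drop, head):
        layer.group = "head"
    net = SequentialNet([adapter, *body, gap, drop, head])
    net.backbone_spec = backbone
    return net


# ---------------------------------------------------------------------------
# Augmentation

def rotate_image(image: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the image center, keeping shape (bilinear, edge-padded)."""
    return ndimage.rotate(image.astype(float), angle, reshape=False, order=1, mode="nearest")


def zoom_image(image: np.ndarray, factor: float) -> np.ndarray:
    """Central zoom by ``factor`` (>1 magnifies), output shape unchanged."""
    h, w = image.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    matrix = np.eye(2) / factor
    offset = center - matrix @ center
    return ndimage.affine_transform(image.astype(float), matrix, offset=offset, order=1, mode="nearest")


def augment(image: np.ndarray, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Random brightness/zoom/rotation for a training image (deterministic per rng state).

    A zero-magnitude config is an exact identity.
    """
    out = np.asarray(image, dtype=float)
    if config.brightness_delta > 0:
        out = np.clip(out * (1.0 + rng.uniform(-config.brightness_delta, config.brightness_delta)), 0, 255)
    if config.zoom > 0:
        out = zoom_image(out, 1.0 + rng.uniform(-config.zoom, config.zoom))
    if config.rotation > 0:
        out = rotate_image(out, rng.uniform(0.0, config.rotation))
    return out


# ---------------------------------------------------------------------------
# Training

def _prep_batch(images: list[np.ndarray], input_size: tuple[int, int]) -> np.ndarray:
    """Resize (bilinear) to the backbone's input size and scale to [0, 1]."""
    h, w = input_size
    out = np.empty((len(images), 1, h, w))
    for i, img in enumerate(images):
        img = np.asarray(img, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        if img.shape != (h, w):
            img = _sk_resize(img, (h, w), order=1, preserve_range=True, anti_aliasing=False)
        out[i, 0] = img / 255.0
    return out


def predict_proba(net: SequentialNet, images: list[np.ndarray], batch_size: int = 32) -> np.ndarray:
    """Per-image abnormality probability; inference mode (no dropout, no augmentation)."""
    input_size = net.backbone_spec.input_size
    probs = []
    for start in range(0, len(images), batch_size):
        xb = _prep_batch(images[start : start + batch_size], input_size)
        z = net.forward(xb, train=False)
        probs.append(sigmoid(z).ravel())
    return np.concatenate(probs) if probs else np.array([])


def _stage_trainability(net: SequentialNet, stage: int, config: TrainConfig) -> None:
    spec: BackboneSpec = net.backbone_spec
    if stage == 1:
        freeze = config.freeze_backbone_stage1
        if freeze is None:
            freeze = spec.pretrained
        groups = {"adapter", "head"} if freeze else {"adapter", "backbone", "head"}
        net.set_trainable(groups)
    else:
        if spec.unfreeze_mode == "head-only":
            net.set_trainable({"adapter", "head"})
        elif spec.unfreeze_mode == "all":
            net.set_trainable({"adapter", "backbone", "head"})
        else:
            net.set_trainable({"adapter", "backbone", "head"}, last_k_backbone=spec.k)


def _run_stage(
    net: SequentialNet,
    X_train: list[np.ndarray],
    y_train: np.ndarray,
    X_val: list[np.ndarray],
    y_val: np.ndarray,
    lr: float,
    config: TrainConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """One early-stopped training stage; restores the best-validation weights."""
    input_size = net.backbone_spec.input_size
    opt = Adam(net, lr=lr)
    best_acc = -np.inf
    best_state = net.state_dict()
    wait = 0
    history: list[dict] = []
    n = len(X_train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_imgs = [augment(X_train[i], config.augmentation, rng) for i in idx]
            xb = _prep_batch(batch_imgs, input_size)
            yb = y_train[idx]
            z = net.forward(xb, train=True, rng=rng)
            loss, dz = bce_with_logits(z, yb)
            net.backward(dz)
            opt.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int(((sigmoid(z).ravel() >= 0.5) == yb).sum())
        val_probs = predict_proba(net, X_val, config.batch_size)
        val_pred = val_probs >= 0.5
        val_acc = float((val_pred == y_val).mean())
        eps = 1e-12
        val_loss = float(-np.mean(y_val * np.log(val_probs + eps) + (1 - y_val) * np.log(1 - val_probs + eps)))
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / n,
                "train_accuracy": epoch_correct / n,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_acc > best_acc:
            best_acc, best_state, wait = val_acc, net.state_dict(), 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    net.load_state_dict(best_state)
    return history


def train_two_stage(
    net: SequentialNet,
    X_train: list[np.ndarray],
    y_train: np.ndarray,
    X_val: list[np.ndarray],
    y_val: np.ndarray,
    config: TrainConfig,
) -> dict[str, list[dict]]:
    """Run the frozen-backbone stage then the low-learning-rate fine-tuning stage."""
    config.validate()
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    for y in (y_train, y_val):
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary (0 = normal, 1 = abnormal)")
    rng = np.random.default_rng(config.seed)
    _stage_trainability(net, 1, config)
    history1 = _run_stage(net, X_train, y_train, X_val, y_val, config.stage1_lr, config, rng)
    _stage_trainability(net, 2, config)
    history2 = _run_stage(net, X_train, y_train, X_val, y_val, config.stage2_lr, config, rng)
    return {"stage1": history1, "stage2": history2}


# ---------------------------------------------------------------------------
# sklearn estimator surface

class EAUSClassifier(ClassifierMixin, BaseEstimator):
    """Binary ultrasound-frame classifier with the two-stage training protocol.

    Accepts a list (or 3-D array) of 2-D grayscale frames in [0, 255]; frames
    are resized to ``input_size`` internally. Follows scikit-learn estimator
    conventions; a validation set may be passed to ``fit`` (as done by the
    cross-validation driver), otherwise ``validation_fraction`` of the
    training data is held out, stratified.
    """

    def __init__(
        self,
        backbone: str = "tiny-scratch",
        input_size: tuple[int, int] = (64, 64),
        pretrained: bool = False,
        unfreeze_mode: str = "all",
        k: int = 3,
        stage1_lr: float = 3e-3,
        stage2_lr: float = 1e-5,
        batch_size: int = 8,
        patience: int = 4,
        max_epochs: int = 100,
        brightness_delta: float = 0.1,
        zoom: float = 0.1,
        rotation: float = 360.0,
        threshold: float = 0.5,
        validation_fraction: float = 1.0 / 6.0,
        freeze_backbone_stage1: Optional[bool] = None,
        seed: int = 0,
    ):
        self.backbone = backbone
        self.input_size = input_size
        self.pretrained = pretrained
        self.unfreeze_mode = unfreeze_mode
        self.k = k
        self.stage1_lr = stage1_lr
        self.stage2_lr = stage2_lr
        self.batch_size = batch_size
        self.patience = patience
        self.max_epochs = max_epochs
        self.brightness_delta = brightness_delta
        self.zoom = zoom
        self.rotation = rotation
        self.threshold = threshold
        self.validation_fraction = validation_fraction
        self.freeze_backbone_stage1 = freeze_backbone_stage1
        self.seed = seed

    # -- spec/config assembly -------------------------------------------------
    def _backbone_spec(self) -> BackboneSpec:
        return BackboneSpec(
            name=self.backbone,
            input_size=tuple(self.input_size),
            pretrained=self.pretrained,
            unfreeze_mode=self.unfreeze_mode,
            k=self.k,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            stage1_lr=self.stage1_lr,
            stage2_lr=self.stage2_lr,
            batch_size=self.batch_size,
            patience=self.patience,
            max_epochs=self.max_epochs,
            augmentation=AugmentConfig(
                brightness_delta=self.brightness_delta, zoom=self.zoom, rotation=self.rotation
            ),
            threshold=self.threshold,
            seed=self.seed,
            freeze_backbone_stage1=self.freeze_backbone_stage1,
        )

    @staticmethod
    def _as_list(X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            X = [X[i] for i in range(X.shape[0])]
        out = []
        for x in X:
            x = np.asarray(x, dtype=float)
            if x.ndim == 3:  # RGB frame: channel-mean grayscale
                x = x.mean(axis=2)
            if x.ndim != 2:
                raise ValueError(f"expected 2-D frames, got shape {x.shape}")
            out.append(x)
        return out

    def fit(self, X, y, X_val=None, y_val=None) -> "EAUSClassifier":
        X = self._as_list(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"expected exactly 2 classes, got {list(self.classes_)}")
        y_bin = (y == self.classes_[1]).astype(int)
        if X_val is None:
            idx_tr, idx_val = train_test_split(
                np.arange(len(X)),
                test_size=self.validation_fraction,
                stratify=y_bin,
                random_state=self.seed,
            )
            X_tr, y_tr = [X[i] for i in idx_tr], y_bin[idx_tr]
            X_va, y_va = [X[i] for i in idx_val], y_bin[idx_val]
        else:
            X_tr, y_tr = X, y_bin
            X_va = self._as_list(X_val)
            y_va = (np.asarray(y_val) == self.classes_[1]).astype(int)
        self.net_ = build_classifier(self._backbone_spec(), seed=self.seed)
        self.history_ = train_two_stage(self.net_, X_tr, y_tr, X_va, y_va, self._train_config())
        self.n_features_in_ = int(np.prod(self.input_size))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        p = predict_proba(self.net_, self._as_list(X), self.batch_size)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= self.threshold).astype(int)]
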