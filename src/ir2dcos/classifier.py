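"""Residual-CNN classification of 2D-COS images.

The network is a small residual CNN: one stem convolution with batch
normalization and ReLU, four residual stages — each a projection
("convolution") block followed by identity blocks, (1, 2, 2, 1) identity
blocks by default for a total of 4 convolution + 6 identity blocks —
then global average pooling and a fully connected softmax head.
Training minimizes cross-entropy with SGD (momentum 0.9), learning rate
0.01 and weight decay 1e-4 by default, for 40 epochs, with optional data
augmentation (random resized crop; transpose flip, valid for symmetric
synchronous maps).

:class:`ResidualCNNClassifier` wraps the engine as a scikit-learn
estimator (``fit`` / ``predict`` / ``predict_proba`` / ``score``), so it
composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn

__all__ = [
    "ModelConfig", "TrainReport", "build_model", "train", "evaluate",
    "predict", "save_model", "load_model", "write_curves",
    "ResidualCNNClassifier",
]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``identity_plan`` gives the identity-block count per stage; each
    stage additionally opens with one convolution block, so the default
    (1, 2, 2, 1) yields 4 convolution + 6 identity residual blocks.
    """

    input_size: int = 224
    n_classes: int = 7
    channels: tuple[int, ...] = (16, 32, 64, 128)
    identity_plan: tuple[int, ...] = (1, 2, 2, 1)
    stem_filter: int = 7
    stem_stride: int = 2
    learning_rate: float = 0.01
    weight_decay: float = 1e-4
    momentum: float = 0.9
    bn_momentum: float = 0.1
    epochs: int = 40
    batch_size: int = 16
    seed: int = 0
    augmentation: tuple[str, ...] = ("resized_crop", "transpose_flip")

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if len(self.channels) != len(self.identity_plan):
            raise ValueError("channels and identity_plan lengths differ")
        unknown = set(self.augmentation) - {"resized_crop", "transpose_flip"}
        if unknown:
            raise ValueError(f"unknown augmentation(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        d["identity_plan"] = list(self.identity_plan)
        d["augmentation"] = list(self.augmentation)
        return d


@dataclass
class TrainReport:
    """Per-epoch accuracy/loss curves plus final external-set metrics."""

    train_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    external_accuracy: float | None = None
    best_test_accuracy: float | None = None
    final_test_accuracy: float | None = None
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    def to_dict(self) -> dict:
        return asdict(self)


def build_model(cfg: ModelConfig) -> nn.ResNet:
    """Instantiate the residual CNN described by ``cfg`` (weights seeded)."""
    model = nn.ResNet(
        n_classes=cfg.n_classes,
        in_ch=3,
        channels=cfg.channels,
        identity_plan=cfg.identity_plan,
        stem_filter=cfg.stem_filter,
        stem_stride=cfg.stem_stride,
        bn_momentum=cfg.bn_momentum,
        seed=cfg.seed,
    )
    counts = model.block_counts()
    if counts["convolution"] != len(cfg.channels):
        raise ValueError("stage plan inconsistent with convolution block count")
    if counts["identity"] != sum(cfg.identity_plan):
        raise ValueError("stage plan inconsistent with identity block count")
    return model


def _as_nchw(X: np.ndarray) -> np.ndarray:
    """Accept (N,H,W,3) uint8/float or (N,3,H,W) float; return float32 NCHW in [0,1]."""
    X = np.asarray(X)
    if X.ndim == 3:
        X = X[None]
    if X.ndim != 4:
        raise ValueError(f"expected image batch, got shape {X.shape}")
    if X.shape[-1] == 3 and X.shape[1] != 3:
        X = X.transpose(0, 3, 1, 2)
    X = X.astype(np.float32)
    if X.max() > 1.5:  # uint8 range
        X = X / 255.0
    return np.ascontiguousarray(X)


def _augment_batch(xb: np.ndarray, kinds: tuple[str, ...],
                   rng: np.random.Generator) -> np.ndarray:
    """Random resized crop (scale 0.9-1.0) and/or transpose flip, per image."""
    if not kinds:
        return xb
    out = xb
    n, c, h, w = out.shape
    if "resized_crop" in kinds:
        out = out.copy()
        for i in range(n):
            scale = rng.uniform(0.9, 1.0)
            side = max(2, int(round(h * np.sqrt(scale))))
            if side < h:
                top = rng.integers(0, h - side + 1)
                left = rng.integers(0, w - side + 1)
                crop = out[i][:, top:top + side, left:left + side]
                coords = np.linspace(0, side - 1, h)
                rr, cc = np.meshgrid(coords, coords, indexing="ij")
                for ch in range(c):
                    out[i, ch] = map_coordinates(crop[ch], [rr, cc], order=1,
                                                 mode="nearest")
    if "transpose_flip" in kinds:
        flips = rng.random(n) < 0.5
        if flips.any():
            out = out.copy() if out is xb else out
            out[flips] = out[flips].transpose(0, 1, 3, 2)
    return out


def _forward_in_batches(model: nn.ResNet, X: np.ndarray,
                        batch_size: int = 64) -> np.ndarray:
    logits = []
    for i in range(0, X.shape[0], batch_size):
        logits.append(model.forward(X[i:i + batch_size]))
    return np.concatenate(logits, axis=0)


def evaluate(model: nn.ResNet, X: np.ndarray, y: np.ndarray,
             class_labels: list | None = None) -> dict:
    """Accuracy, mean cross-entropy and confusion counts on an image set."""
    X = _as_nchw(X)
    y = np.asarray(y, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty image set")
    model.set_training(False)
    logits = _forward_in_batches(model, X)
    loss, _ = nn.cross_entropy(logits, y)
    pred = logits.argmax(axis=1)
    k = model.n_classes
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y, pred):
        confusion[t, p] += 1
    return {
        "accuracy": float((pred == y).mean()),
        "loss": float(loss),
        "confusion": confusion,
        "predictions": pred,
        "class_labels": class_labels,
    }


def predict(model: nn.ResNet, image: np.ndarray) -> np.ndarray:
    """Class probability vector (softmax) for one image or a batch."""
    single = np.asarray(image).ndim == 3
    X = _as_nchw(image)
    model.set_training(False)
    p = nn.softmax(_forward_in_batches(model, X))
    return p[0] if single else p


def train(
    model: nn.ResNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    cfg: ModelConfig,
) -> TrainReport:
    """SGD training loop; logs per-epoch train/test accuracy and loss.

    Train-set metrics are the running average over the epoch's
    minibatches (training mode); test metrics are computed in evaluation
    mode after each epoch.  A class missing from the training set aborts
    before training starts.  Fixed ``cfg.seed`` makes runs bit-identical
    on one device.
    """
    X_train = _as_nchw(X_train)
    X_test = _as_nchw(X_test)
    y_train = np.asarray(y_train, dtype=int)
    y_test = np.asarray(y_test, dtype=int)
    if X_train.shape[0] == 0 or X_test.shape[0] == 0:
        raise ValueError("train and test image sets must be nonempty")
    present = set(np.unique(y_train).tolist())
    missing = set(range(cfg.n_classes)) - present
    if missing:
        raise ValueError(f"classes missing from training set: {sorted(missing)}")

    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.SGD(model.parameters(), lr=cfg.learning_rate,
                 momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    report = TrainReport(config=cfg.to_dict(), seed=cfg.seed)
    n = X_train.shape[0]
    for _epoch in range(cfg.epochs):
        model.set_training(True)
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = _augment_batch(X_train[idx], cfg.augmentation, rng)
            yb = y_train[idx]
            opt.zero_grad()
            logits = model.forward(xb)
            loss, dlogits = nn.cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
        report.train_loss.append(float(np.sum(losses) / n))
        report.train_accuracy.append(correct / n)
        model.recalibrate_bn(X_train)
        test_metrics = evaluate(model, X_test, y_test)
        report.test_loss.append(test_metrics["loss"])
        report.test_accuracy.append(test_metrics["accuracy"])
    report.final_test_accuracy = report.test_accuracy[-1]
    report.best_test_accuracy = float(max(report.test_accuracy))
    return report


def save_model(model: nn.ResNet, cfg: ModelConfig, path: str | Path,
               classes: list | None = None) -> Path:
    """Checkpoint: parameter arrays + BN running stats (.npz) and a JSON
    config snapshot alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    for i, bn in enumerate(model.bn_layers()):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    np.savez(path, **arrays)
    meta = {"config": cfg.to_dict()}
    if classes is not None:
        meta["classes"] = [str(c) for c in classes]
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_model(path: str | Path) -> tuple[nn.ResNet, ModelConfig, list[str] | None]:
    """Rebuild a checkpointed model; returns (model, config, class labels)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    d = dict(meta["config"])
    for k in ("channels", "identity_plan", "augmentation"):
        d[k] = tuple(d[k])
    cfg = ModelConfig(**d)
    model = build_model(cfg)
    with np.load(path) as data:
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"param_{i}"]
        for i, bn in enumerate(model.bn_layers()):
            bn.running_mean[...] = data[f"bn_mean_{i}"]
            bn.running_var[...] = data[f"bn_var_{i}"]
    return model, cfg, meta.get("classes")


def write_curves(report: TrainReport, out_dir: str | Path,
                 stem: str = "curves") -> tuple[Path, Path]:
    """Write per-epoch accuracy/loss curves as CSV and a two-panel PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "epoch": np.arange(1, len(report.train_accuracy) + 1),
        "train_accuracy": report.train_accuracy,
        "test_accuracy": report.test_accuracy,
        "train_loss": report.train_loss,
        "test_loss": report.test_loss,
    })
    csv_path = out_dir / f"{stem}.csv"
    df.to_csv(csv_path, index=False)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.plot(df["epoch"], df["train_accuracy"], label="train")
    ax1.plot(df["epoch"], df["test_accuracy"], label="test")
    ax1.set_xlabel("epoch"), ax1.set_ylabel("accuracy"), ax1.legend()
    ax2.plot(df["epoch"], df["train_loss"], label="train")
    ax2.plot(df["epoch"], df["test_loss"], label="test")
    ax2.set_xlabel("epoch"), ax2.set_ylabel("cross-entropy"), ax2.legend()
    fig.tight_layout()
    png_path = out_dir / f"{stem}.png"
    fig.savefig(png_path, dpi=100)
    plt.close(fig)
    return csv_path, png_path


class ResidualCNNClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn estimator facade over the residual CNN.

    ``fit(X, y)`` takes a stack of RGB images — ``(n, H, W, 3)`` uint8
    or ``(n, 3, H, W)`` float — and string or integer labels.  An
    optional held-out set ``(X_val, y_val)`` drives the per-epoch test
    curve; when absent the training set is reused for the curve.

    Fitted attributes: ``classes_``, ``model_``, ``report_``,
    ``n_features_in_`` (flattened pixel count).
    """

    def __init__(
        self,
        input_size: int = 224,
        channels: tuple[int, ...] = (16, 32, 64, 128),
        identity_plan: tuple[int, ...] = (1, 2, 2, 1),
        stem_filter: int = 7,
        stem_stride: int = 2,
        learning_rate: float = 0.01,
        weight_decay: float = 1e-4,
        momentum: float = 0.9,
        bn_momentum: float = 0.1,
        epochs: int = 40,
        batch_size: int = 16,
        seed: int = 0,
        augmentation: tuple[str, ...] = ("resized_crop", "transpose_flip"),
    ):
        self.input_size = input_size
        self.channels = channels
        self.identity_plan = identity_plan
        self.stem_filter = stem_filter
        self.stem_stride = stem_stride
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.momentum = momentum
        self.bn_momentum = bn_momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.augmentation = augmentation

    def _config(self, n_classes: int) -> ModelConfig:
        return ModelConfig(
            input_size=self.input_size,
            n_classes=n_classes,
            channels=tuple(self.channels),
            identity_plan=tuple(self.identity_plan),
            stem_filter=self.stem_filter,
            stem_stride=self.stem_stride,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            momentum=self.momentum,
            bn_momentum=self.bn_momentum,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed,
            augmentation=tuple(self.augmentation),
        )

    def fit(self, X, y, X_val=None, y_val=None):
        X = _as_nchw(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        cfg = self._config(len(self.classes_))
        self.model_ = build_model(cfg)
        if X_val is None:
            Xv, yv = X, y_idx
        else:
            Xv = _as_nchw(X_val)
            yv = np.searchsorted(self.classes_, np.asarray(y_val))
        self.report_ = train(self.model_, X, y_idx, Xv, yv, cfg)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        return predict(self.model_, _as_nchw(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())
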