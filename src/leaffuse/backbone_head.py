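"""The "mutated" transfer-learning classification head.

Transfer learning keeps a pre-trained convolutional backbone frozen and
replaces ("mutates") its top layers with a task-specific head:

    global average pool -> dense(256, relu) -> dense(256, relu)
    -> dropout(0.5) -> dense(K, softmax)

The head is the only trainable part; its parameter count is therefore the
model's trainable-parameter budget and is accounted for exactly by
:func:`count_head_params`.  Training uses categorical cross-entropy with
the Adagrad optimizer, early stopping on validation accuracy, and
learning-rate reduction on plateau.

The :class:`FeatureExtractor` protocol decouples the head from any deep
learning framework; :class:`RandomProjectionExtractor` is a deterministic,
dependency-free extractor (fixed random projection of downsampled pixels)
that exercises the full training path in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .data_pipeline import LabeledDataset, rescale, resize_to_input

__all__ = [
    "FeatureExtractor",
    "HeadSpec",
    "MutatedHead",
    "ParamCount",
    "RandomProjectionExtractor",
    "TrainConfig",
    "TrainedClassifier",
    "build_head",
    "count_head_params",
    "predict_proba",
    "train_classifier",
]


@runtime_checkable
class FeatureExtractor(Protocol):
    """Frozen map from a 224x224 RGB image to a fixed-length feature vector."""

    feature_dim: int

    def extract(self, img: np.ndarray) -> np.ndarray: ...


class RandomProjectionExtractor:
    """Deterministic test-scale feature extractor.

    Downsamples the image to ``grid x grid`` by block averaging and applies
    a fixed random projection to ``feature_dim`` dimensions.  Frozen by
    construction; the projection depends only on ``seed``.
    """

    def __init__(self, feature_dim: int = 64, grid: int = 8, seed: int = 0) -> None:
        self.feature_dim = int(feature_dim)
        self.grid = int(grid)
        rng = np.random.default_rng(seed)
        d_in = 3 * self.grid * self.grid
        self._proj = rng.standard_normal((d_in, self.feature_dim)) / np.sqrt(d_in)

    def extract(self, img: np.ndarray) -> np.ndarray:
        img = resize_to_input(img)
        x = rescale(img)
        side = x.shape[0]
        block = side // self.grid
        x = x[: block * self.grid, : block * self.grid]
        x = x.reshape(self.grid, block, self.grid, block, 3).mean(axis=(1, 3))
        return x.reshape(-1) @ self._proj

    def extract_batch(self, imgs: Sequence[np.ndarray]) -> np.ndarray:
        return np.stack([self.extract(im) for im in imgs])


@dataclass(frozen=True)
class HeadSpec:
    """Architecture of the mutated head."""

    feature_dim: int
    num_classes: int
    hidden_units: tuple[int, int] = (256, 256)
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.feature_dim < 1 or self.num_classes < 1:
            raise ValueError("feature_dim and num_classes must be positive")
        if any(h < 1 for h in self.hidden_units):
            raise ValueError("hidden_units must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class ParamCount:
    total: int
    trainable: int
    non_trainable: int

    def __post_init__(self) -> None:
        if self.total != self.trainable + self.non_trainable:
            raise ValueError("total must equal trainable + non_trainable")
        if min(self.total, self.trainable, self.non_trainable) < 0:
            raise ValueError("parameter counts must be non-negative")


def count_head_params(spec: HeadSpec) -> ParamCount:
    """Exact weight accounting for the head.

    Each dense layer contributes ``fan_in * units + units`` (weights plus
    biases); pooling and dropout contribute nothing.  With the default
    (256, 256) hidden stack this is
    ``(feature_dim*256 + 256) + (256*256 + 256) + (256*K + K)``.
    """
    h1, h2 = spec.hidden_units
    dense1 = spec.feature_dim * h1 + h1
    dense2 = h1 * h2 + h2
    out = h2 * spec.num_classes + spec.num_classes
    trainable = dense1 + dense2 + out
    return ParamCount(total=trainable, trainable=trainable, non_trainable=0)


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule for the head (Adagrad, early stopping, LR plateau)."""

    batch_size: int = 16
    base_lr: float = 0.01857
    max_epochs: int = 30
    early_stop_patience: int = 5
    lr_reduce_on_plateau: bool = True
    lr_reduce_factor: float = 0.5
    lr_reduce_patience: int = 3
    min_lr: float = 1e-5
    optimizer: str = "adagrad"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.early_stop_patience < 1:
            raise ValueError("batch_size and patience must be at least 1")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.optimizer != "adagrad":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MutatedHead:
    """dense(h1, relu) -> dense(h2, relu) -> dropout -> dense(K, softmax).

    Inputs may be feature vectors (d,) or feature maps (H, W, d); feature
    maps are global-average-pooled first, mirroring the GlobalAveragePooling2D
    layer that precedes the dense stack.
    """

    def __init__(self, spec: HeadSpec, rng: np.random.Generator | None = None,
                 init: str = "glorot") -> None:
        self.spec = spec
        rng = rng if rng is not None else np.random.default_rng(0)
        h1, h2 = spec.hidden_units
        dims = [(spec.feature_dim, h1), (h1, h2), (h2, spec.num_classes)]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in dims:
            if init == "zeros":
                w = np.zeros((d_in, d_out))
            else:
                limit = np.sqrt(6.0 / (d_in + d_out))
                w = rng.uniform(-limit, limit, size=(d_in, d_out))
            self.weights.append(w)
            self.biases.append(np.zeros(d_out))

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Return class probabilities; caches activations when training.

        Accepts feature vectors ``(d,)`` / ``(n, d)`` or feature maps
        ``(H, W, d)`` / ``(n, H, W, d)``; maps are global-average-pooled.
        """
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:  # single feature map
            x = x.reshape(-1, x.shape[-1]).mean(axis=0)[None, :]
        elif x.ndim == 4:  # batch of feature maps
            x = x.reshape(x.shape[0], -1, x.shape[-1]).mean(axis=1)
        else:
            x = np.atleast_2d(x)
        a1 = np.maximum(x @ self.weights[0] + self.biases[0], 0.0)
        a2 = np.maximum(a1 @ self.weights[1] + self.biases[1], 0.0)
        if training and self.spec.dropout_rate > 0:
            if dropout_rng is None:
                raise ValueError("dropout_rng required when training")
            keep = 1.0 - self.spec.dropout_rate
            mask = (dropout_rng.random(a2.shape) < keep) / keep  # inverted dropout
            a2d = a2 * mask
        else:
            mask = None
            a2d = a2
        logits = a2d @ self.weights[2] + self.biases[2]
        probs = _softmax(logits)
        self._cache = (x, a1, a2, mask, a2d, probs)
        return probs

    def backward(self, y_onehot: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gradients of mean cross-entropy w.r.t. each (W, b), from the cache."""
        x, a1, a2, mask, a2d, probs = self._cache
        n = x.shape[0]
        dlogits = (probs - y_onehot) / n
        dw3 = a2d.T @ dlogits
        db3 = dlogits.sum(axis=0)
        da2d = dlogits @ self.weights[2].T
        da2 = da2d * mask if mask is not None else da2d
        da2[a2 <= 0] = 0.0
        dw2 = a1.T @ da2
        db2 = da2.sum(axis=0)
        da1 = da2 @ self.weights[1].T
        da1[a1 <= 0] = 0.0
        dw1 = x.T @ da1
        db1 = da1.sum(axis=0)
        return [(dw1, db1), (dw2, db2), (dw3, db3)]

    def get_params(self) -> list[np.ndarray]:
        return [w.copy() for w in self.weights] + [b.copy() for b in self.biases]

    def set_params(self, params: list[np.ndarray]) -> None:
        k = len(self.weights)
        self.weights = [p.copy() for p in params[:k]]
        self.biases = [p.copy() for p in params[k:]]


def build_head(spec: HeadSpec, seed: int = 0, init: str = "glorot") -> MutatedHead:
    return MutatedHead(spec, rng=np.random.default_rng(seed), init=init)


class _Adagrad:
    """Adagrad with per-parameter accumulated squared gradients.

    Accumulator initialized at 0.1, matching the Keras convention.
    """

    def __init__(self, lr: float, initial_accumulator: float = 0.1,
                 eps: float = 1e-7) -> None:
        self.lr = lr
        self.eps = eps
        self.initial_accumulator = initial_accumulator
        self._acc: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._acc is None:
            self._acc = [np.full_like(p, self.initial_accumulator) for p in params]
        for p, g, a in zip(params, grads, self._acc):
            a += g * g
            p -= self.lr * g / (np.sqrt(a) + self.eps)


@dataclass
class TrainedClassifier:
    """A trained head bundled with its frozen extractor and label names."""

    extractor: FeatureExtractor
    head: MutatedHead
    class_names: list[str]
    config: TrainConfig
    history: dict[str, list[float]] = field(default_factory=dict)

    def predict_proba(self, imgs: Sequence[np.ndarray]) -> np.ndarray:
        feats = np.stack([self.extractor.extract(im) for im in imgs])
        return self.head.forward(feats, training=False)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(out_dir / "weights.npz",
                 **{f"param_{i}": p for i, p in enumerate(self.head.get_params())})
        sidecar = {
            "head_spec": asdict(self.head.spec),
            "class_names": self.class_names,
            "train_config": asdict(self.config),
            "history": self.history,
        }
        (out_dir / "model.json").write_text(json.dumps(sidecar, indent=2))


def _features_and_labels(
    extractor: FeatureExtractor, ds: LabeledDataset
) -> tuple[np.ndarray, np.ndarray]:
    feats = np.stack([extractor.extract(img) for img, _ in ds.samples])
    labels = ds.labels()
    return feats, labels


def train_classifier(
    extractor: FeatureExtractor,
    head: MutatedHead,
    train: LabeledDataset,
    val: LabeledDataset,
    cfg: TrainConfig,
) -> tuple[TrainedClassifier, dict[str, list[float]]]:
    """Train the head on frozen features with early stopping.

    An epoch "improves" when validation accuracy strictly exceeds the best
    seen so far; after ``early_stop_patience`` consecutive non-improving
    epochs training stops and the best-epoch weights are restored.  The
    learning rate halves after ``lr_reduce_patience`` stagnant epochs
    (floored at ``min_lr``) when plateau reduction is on.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    if train.class_names != val.class_names:
        raise ValueError("train and validation class names differ")
    k = len(train.class_names)
    x_train, y_train = _features_and_labels(extractor, train)
    x_val, y_val = _features_and_labels(extractor, val)
    y_onehot = np.eye(k)[y_train]

    rng = np.random.default_rng(cfg.seed)
    opt = _Adagrad(lr=cfg.base_lr)
    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": [], "lr": []
    }
    best_acc = -np.inf
    best_params = head.get_params()
    stall = 0
    lr_stall = 0
    n = len(x_train)

    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs = head.forward(x_train[idx], training=True, dropout_rng=rng)
            clipped = np.clip(probs[np.arange(len(idx)), y_train[idx]], 1e-12, None)
            epoch_loss += float(-np.log(clipped).sum())
            correct += int((probs.argmax(axis=1) == y_train[idx]).sum())
            grads = head.backward(y_onehot[idx])
            flat_params = head.weights + head.biases
            flat_grads = [g for g, _ in grads] + [b for _, b in grads]
            opt.step(flat_params, flat_grads)

        val_probs = head.forward(x_val, training=False)
        val_clip = np.clip(val_probs[np.arange(len(x_val)), y_val], 1e-12, None)
        val_loss = float(-np.log(val_clip).mean())
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(correct / n)
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        history["lr"].append(opt.lr)

        if val_acc > best_acc:
            best_acc = val_acc
            best_params = head.get_params()
            stall = 0
            lr_stall = 0
        else:
            stall += 1
            lr_stall += 1
            if cfg.lr_reduce_on_plateau and lr_stall >= cfg.lr_reduce_patience:
                opt.lr = max(cfg.min_lr, opt.lr * cfg.lr_reduce_factor)
                lr_stall = 0
            if stall >= cfg.early_stop_patience:
                break

    head.set_params(best_params)
    model = TrainedClassifier(
        extractor=extractor, head=head, class_names=list(train.class_names),
        config=cfg, history=history,
    )
    return model, history


def predict_proba(
    model: TrainedClassifier, imgs: Sequence[np.ndarray]
) -> np.ndarray:
    """Class probabilities for a batch of images; rows sum to 1."""
    return model.predict_proba(imgs)
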