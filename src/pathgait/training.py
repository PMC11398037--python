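"""Training loop and evaluation metrics for the gait classifier.

Training follows the reference recipe: Adam, cross-entropy loss, minibatches
of 32, stratified 80/20 train/test split, dropout 0.2. When the backbone is
frozen (transfer learning, or the fixed-random-features regime used on the
synthetic benchmark), backbone feature maps are computed once per sample and
cached, and only the attention block and head are optimized — a large
speed-up at identical gradients.

Evaluation reports the multiclass confusion matrix and, from it, accuracy
plus per-class and macro precision, sensitivity, specificity and F1:

    accuracy     = sum_i TP_i / N
    precision_i  = TP_i / (TP_i + FP_i)
    sensitivity_i= TP_i / (TP_i + FN_i)
    specificity_i= TN_i / (TN_i + FP_i)
    F1_i         = 2 * P_i * R_i / (P_i + R_i)

macro metrics are unweighted class means; a class with a zero denominator
contributes 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn.layers import Dropout, no_grad, softmax, softmax_cross_entropy
from .nn.model import GaitRecognitionModel
from .nn.optim import Adam


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the reference recipe)."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class TrainHistory:
    """Per-epoch mean loss and training accuracy."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


@dataclass
class ConfusionMatrix:
    """counts[i, j] = samples of true class i predicted as class j."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.class_names)
        if self.counts.shape != (n, n):
            raise ValueError("confusion matrix must be n_classes x n_classes")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Macro metrics in percent, plus the per-class breakdown."""

    accuracy: float
    macro_precision: float
    macro_sensitivity: float
    macro_specificity: float
    macro_f1: float
    per_class: dict[str, dict[str, float]]

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class,
        }


def split_indices(labels: np.ndarray, test_fraction: float = 0.2,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split; returns (train_idx, test_idx), disjoint, exhaustive.

    Per class, round(n * test_fraction) samples (at least 1) go to the test
    set. Raises if any class has fewer than 2 samples.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_test = min(idx.size - 1, max(1, round(idx.size * test_fraction)))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def split_dataset(samples: list, labels: np.ndarray, config: TrainConfig):
    """Stratified split of parallel sample/label lists per the config."""
    train_idx, test_idx = split_indices(np.asarray(labels), config.test_fraction,
                                        config.seed)
    take = lambda idx: ([samples[i] for i in idx], np.asarray(labels)[idx])
    return take(train_idx), take(test_idx)


def compute_features(model: GaitRecognitionModel, X: np.ndarray,
                     batch_size: int = 32) -> np.ndarray:
    """Backbone feature maps for a stack of images, in fixed batch order.

    Batch normalization uses batch statistics: without trained running
    statistics (random or freshly loaded backbones) they are the only
    meaningful normalization, and with a fixed batch partition the result is
    deterministic.
    """
    was_training = model.training
    model.backbone.train(True)
    feats = []
    with no_grad():
        for i in range(0, len(X), batch_size):
            feats.append(model.extract_features(X[i:i + batch_size]))
    model.backbone.train(was_training)
    return np.concatenate(feats, axis=0)


def train(model: GaitRecognitionModel, train_set: tuple[np.ndarray, np.ndarray],
          config: TrainConfig, cached_features: np.ndarray | None = None) -> TrainHistory:
    """Minibatch Adam training; returns per-epoch loss/accuracy history.

    ``train_set`` is (X, y) with X of shape (N, C, H, W) scaled to [0, 1] and
    integer labels y. With a frozen backbone, features are computed once and
    reused every epoch (pass ``cached_features`` to reuse an existing cache).
    All randomness (shuffling, dropout) derives from ``config.seed``.
    """
    X, y = train_set
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(X) != len(y):
        raise ValueError("X and y must have matching lengths")
    rng = np.random.default_rng(config.seed)
    for m in [model] + list(_walk(model)):
        if isinstance(m, Dropout):
            m.reseed(int(rng.integers(2**31 - 1)))

    frozen = not any(p.trainable for p in model.backbone.parameters())
    feats = None
    if frozen:
        feats = (cached_features if cached_features is not None
                 else compute_features(model, X, config.batch_size))

    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    n = len(X)
    for _ in range(config.epochs):
        model.train(True)
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            yb = y[idx]
            if frozen:
                logits = model.head_forward(feats[idx])
            else:
                logits = model.forward(X[idx])
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss; check inputs/learning rate")
            model.zero_grad()
            if frozen:
                model.head_backward(dlogits)
            else:
                model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(correct / n)
    model.train(False)
    return history


def _walk(module):
    for m in module.modules():
        yield m
        yield from _walk(m)


def predict(model: GaitRecognitionModel, X: np.ndarray, batch_size: int = 32,
            cached_features: np.ndarray | None = None) -> np.ndarray:
    """Argmax class predictions with the head in evaluation mode."""
    model.train(False)
    feats = (cached_features if cached_features is not None
             else compute_features(model, np.asarray(X, dtype=np.float64), batch_size))
    preds = []
    with no_grad():
        for i in range(0, len(feats), batch_size):
            logits = model.head_forward(feats[i:i + batch_size])
            preds.append(logits.argmax(axis=1))
    return np.concatenate(preds)


def confusion_matrix(model: GaitRecognitionModel, test_set: tuple[np.ndarray, np.ndarray],
                     class_names: list[str], batch_size: int = 32) -> ConfusionMatrix:
    """Tabulate argmax predictions against true labels."""
    X, y = test_set
    preds = predict(model, X, batch_size)
    return confusion_from_predictions(np.asarray(y), preds, class_names)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                               class_names: list[str]) -> ConfusionMatrix:
    k = len(class_names)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        counts[t, p] += 1
    return ConfusionMatrix(counts, list(class_names))


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy and per-class/macro precision, sensitivity, specificity, F1 (%)."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = counts.shape[0]
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def safe_div(num, den, name):
        out = np.zeros(k)
        for i in range(k):
            if den[i] == 0:
                warnings.warn(f"{name} undefined for class {cm.class_names[i]!r} "
                              "(zero denominator); counting as 0", stacklevel=3)
            else:
                out[i] = num[i] / den[i]
        return out

    precision = safe_div(tp, tp + fp, "precision")
    sensitivity = safe_div(tp, tp + fn, "sensitivity")
    specificity = safe_div(tn, tn + fp, "specificity")
    f1 = np.zeros(k)
    for i in range(k):
        if precision[i] + sensitivity[i] > 0:
            f1[i] = 2 * precision[i] * sensitivity[i] / (precision[i] + sensitivity[i])

    per_class = {
        name: {
            "precision": 100.0 * precision[i],
            "sensitivity": 100.0 * sensitivity[i],
            "specificity": 100.0 * specificity[i],
            "f1": 100.0 * f1[i],
        }
        for i, name in enumerate(cm.class_names)
    }
    return MetricsReport(
        accuracy=100.0 * tp.sum() / total,
        macro_precision=100.0 * precision.mean(),
        macro_sensitivity=100.0 * sensitivity.mean(),
        macro_specificity=100.0 * specificity.mean(),
        macro_f1=100.0 * f1.mean(),
        per_class=per_class,
    )
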