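"""Training protocol and evaluation metrics.

Training follows the study protocol: AdamW (decoupled weight decay) on
cross-entropy, learning rate 0.001, 100 epochs, a stratified 80/20
train/validation split, light augmentation (horizontal/vertical flips and
rotations up to +-15 degrees) on the training stream only, and checkpointing
of the weights at the epoch with the highest validation accuracy.

The convergence score summarises a validation-accuracy curve as its
normalised trapezoidal integral over the epoch axis: a curve that reaches a
high plateau early integrates to a larger value than one that climbs late,
so earlier convergence scores higher.  Evaluation reports a confusion matrix
and macro-averaged (unweighted class mean) precision, recall and F1.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .models import Model
from .synthetic_data import ImageDataset

__all__ = ["TrainConfig", "TrainingHistory", "EvalReport", "AdamW",
           "stratified_split", "train", "convergence_score", "evaluate",
           "metrics_from_confusion", "softmax_cross_entropy"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 100
    train_fraction: float = 0.8
    batch_size: int = 32
    weight_decay: float = 1e-4
    augmentation: bool = True
    max_rotation_deg: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch curves; ``best_epoch`` indexes the highest validation
    accuracy (earliest epoch on ties)."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    @property
    def epochs(self) -> int:
        return len(self.val_acc)

    @property
    def best_epoch(self) -> int:
        if not self.val_acc:
            raise ValueError("empty history has no best epoch")
        return int(np.argmax(self.val_acc))

    @property
    def best_val_accuracy(self) -> float:
        return float(self.val_acc[self.best_epoch])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "train_acc", "val_acc"])
            for i in range(self.epochs):
                w.writerow([i, self.train_loss[i], self.train_acc[i],
                            self.val_acc[i]])


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------

def stratified_split(dataset: ImageDataset, fraction: float, seed: int
                     ) -> tuple[ImageDataset, ImageDataset]:
    """Per class, floor(fraction * n_c) samples to train, the rest to
    validation; shuffling is seeded, membership disjoint and exhaustive."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.asarray(dataset.labels)
    train_idx, val_idx = [], []
    for c in range(len(dataset.class_names)):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            raise ValueError(
                f"class {dataset.class_names[c]!r} has no samples")
        if idx.size < 2:
            raise ValueError(
                f"class {dataset.class_names[c]!r} needs >= 2 samples to "
                f"split")
        idx = rng.permutation(idx)
        k = int(np.floor(fraction * idx.size))
        train_idx.extend(idx[:k])
        val_idx.extend(idx[k:])
    return dataset.subset(np.array(train_idx)), dataset.subset(
        np.array(val_idx))


# ---------------------------------------------------------------------------
# Optimiser and loss
# ---------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay.

    Decay is applied only to matrix-valued weights (each layer declares them
    via ``decay_params``); biases, normalisation scales and positional tables
    are exempt, the common convention for transformer training.
    """

    def __init__(self, model: Model, lr: float = 0.001,
                 weight_decay: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for lyr, k, p in model.parameters():
            key = f"{lyr.name}/{k}"
            self.m[key] = np.zeros_like(p)
            self.v[key] = np.zeros_like(p)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for lyr, k, p in self.model.parameters():
            key = f"{lyr.name}/{k}"
            g = lyr.grads.get(k)
            if g is None:
                continue
            m = self.m[key] = b1 * self.m[key] + (1 - b1) * g
            v = self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if k in lyr.decay_params:
                update = update + self.wd * p
            lyr.params[k] = p - self.lr * update


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=-1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-300).mean()
    d = probs.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), d / n


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment_batch(images: np.ndarray, rng: np.random.Generator,
                  max_rotation_deg: float = 15.0) -> np.ndarray:
    """Random horizontal/vertical flips and small rotations, per image."""
    out = images.copy()
    for i in range(out.shape[0]):
        if rng.random() < 0.5:
            out[i] = out[i, :, ::-1]
        if rng.random() < 0.5:
            out[i] = out[i, ::-1]
        angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
        if abs(angle) > 1e-3:
            out[i] = ndimage.rotate(out[i], angle, axes=(0, 1),
                                    reshape=False, order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(model: Model, data: ImageDataset, cfg: TrainConfig,
          val_data: ImageDataset | None = None
          ) -> tuple[dict[str, np.ndarray], TrainingHistory]:
    """Train a built model and return (best weights, history).

    If ``val_data`` is None the dataset is stratified-split internally with
    ``cfg.train_fraction``.  The model is left holding the best-validation
    weights.  Train loss is the batch average seen by the optimiser (with
    augmentation and dropout active); train and validation accuracy are both
    measured at epoch end on clean images in inference mode, so the two
    curves are comparable.
    """
    labels = np.asarray(data.labels)
    n_classes = model.spec.n_classes
    if labels.size and labels.max() >= n_classes:
        raise ValueError(
            f"label {labels.max()} out of range for {n_classes} classes")

    if val_data is None:
        train_set, val_set = stratified_split(data, cfg.train_fraction,
                                              cfg.seed)
    else:
        train_set, val_set = data, val_data

    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history = TrainingHistory()
    best_weights = model.get_weights()
    best_acc = -1.0

    x_train = np.asarray(train_set.images, dtype=np.float64)
    y_train = np.asarray(train_set.labels)
    n = x_train.shape[0]

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses, seen = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            if cfg.augmentation:
                xb = augment_batch(xb, rng, cfg.max_rotation_deg)
            model.zero_grads()
            logits = model.forward(xb, train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            seen += len(idx)
        history.train_loss.append(sum(losses) / seen)
        history.train_acc.append(float(
            (predict_in_batches(model, x_train) == y_train).mean()))

        val_acc = float((predict_in_batches(model, val_set.images)
                         == np.asarray(val_set.labels)).mean())
        history.val_acc.append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_weights = model.get_weights()

    if cfg.epochs > 0:
        model.set_weights(best_weights)
    return best_weights, history


def predict_in_batches(model: Model, images, batch_size: int = 64
                       ) -> np.ndarray:
    x = np.asarray(images, dtype=np.float64)
    preds = [model.predict(x[i:i + batch_size])
             for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(preds) if preds else np.array([], dtype=int)


# ---------------------------------------------------------------------------
# Convergence score
# ---------------------------------------------------------------------------

def convergence_score(history) -> float:
    """Normalised integral of the validation-accuracy curve.

    Trapezoidal integral over the epoch axis divided by (epochs - 1); a
    single-epoch history scores its own accuracy.  Bounded by the maximum
    accuracy, so it lies in [0, 1].
    """
    acc = np.asarray(history.val_acc if isinstance(history, TrainingHistory)
                     else history, dtype=float)
    if acc.size == 0:
        raise ValueError("convergence score needs at least one epoch")
    if acc.size == 1:
        return float(acc[0])
    return float(np.trapezoid(acc) / (acc.size - 1))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix (rows = true class) and macro-averaged metrics.

    Per class, precision = TP/(TP+FP) and recall = TP/(TP+FN); F1 is their
    harmonic mean, with the 0-convention when a denominator vanishes.  Macro
    averages are unweighted class means (the averaging choice is recorded in
    ``averaging``).  ``zero_division_classes`` flags classes never predicted
    or never present.
    """

    confusion_matrix: np.ndarray
    class_names: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    zero_division_classes: tuple[int, ...]
    averaging: str = "macro (unweighted class mean)"

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    @property
    def accuracy(self) -> float:
        cm = self.confusion_matrix
        return float(np.trace(cm) / cm.sum())

    def to_json(self) -> str:
        return json.dumps({
            "averaging": self.averaging,
            "class_names": list(self.class_names),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "zero_division_classes": list(self.zero_division_classes),
        })

    def to_text(self) -> str:
        lines = [f"averaging: {self.averaging}",
                 f"{'class':<16}{'precision':>10}{'recall':>10}{'F1':>10}"]
        for i, name in enumerate(self.class_names):
            flag = " *" if i in self.zero_division_classes else ""
            lines.append(f"{name:<16}{self.precision[i]:>10.4f}"
                         f"{self.recall[i]:>10.4f}{self.f1[i]:>10.4f}{flag}")
        lines.append(f"{'macro':<16}{self.macro_precision:>10.4f}"
                     f"{self.macro_recall:>10.4f}{self.macro_f1:>10.4f}")
        lines.append(f"accuracy: {self.accuracy:.4f}")
        if self.zero_division_classes:
            lines.append("* class never predicted or never present; "
                         "metric set to 0")
        return "\n".join(lines)


def metrics_from_confusion(cm: np.ndarray,
                           class_names: tuple[str, ...] | None = None
                           ) -> EvalReport:
    """Per-class and macro metrics from a confusion matrix (rows = truth)."""
    cm = np.asarray(cm, dtype=np.int64)
    k = cm.shape[0]
    if class_names is None:
        class_names = tuple(f"class_{i}" for i in range(k))
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    flagged = tuple(int(i) for i in range(k)
                    if (tp + fp)[i] == 0 or (tp + fn)[i] == 0)
    return EvalReport(cm, tuple(class_names), precision, recall, f1, flagged)


def evaluate(model: Model, data: ImageDataset, batch_size: int = 64
             ) -> EvalReport:
    """Confusion matrix and macro metrics of arg-max predictions."""
    labels = np.asarray(data.labels)
    if labels.size == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    preds = predict_in_batches(model, data.images, batch_size)
    k = len(data.class_names)
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (labels, preds), 1)
    return metrics_from_confusion(cm, tuple(data.class_names))
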