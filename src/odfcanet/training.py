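"""Training loop and evaluation metrics.

Training is plain mini-batch SGD with momentum at a fixed learning rate
(no schedule), with the softmax cross-entropy loss. Evaluation reports a
confusion matrix plus per-class precision, recall and specificity and the
mean accuracy; cross-validation is stratified k-fold with one freshly
seeded model per fold, averaged by metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .autodiff import Tensor
from .nn import Module, SGD

__all__ = [
    "TrainConfig",
    "EvalReport",
    "softmax",
    "cross_entropy_loss",
    "confusion_matrix",
    "per_class_metrics",
    "evaluate",
    "predict",
    "recalibrate_bn",
    "train",
    "run_kfold_cv",
]


@dataclass
class TrainConfig:
    """Optimization settings. The learning rate is fixed for the whole run."""

    epochs: int = 35
    lr: float = 0.001
    momentum: float = 0.9
    batch_size: int = 32
    weight_decay: float = 0.0
    optimizer: str = "sgd"
    bn_recalibrate: bool = True
    seed: int = 0
    folds: int = 4

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.folds < 2:
            raise ValueError(f"need at least 2 folds, got {self.folds}")
        if self.optimizer != "sgd":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def softmax(logits) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(probs, y_onehot) -> float:
    """Loss = -sum_i y_i log P_i (natural log), for one probability vector.

    ``probs`` must be a probability vector and ``y_onehot`` a one-hot vector;
    probabilities are clamped below at 1e-12 before the log.
    """
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(y_onehot, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {y.shape}")
    if not (np.all((y == 0) | (y == 1)) and np.isclose(y.sum(), 1.0)):
        raise ValueError("y must be a one-hot vector")
    return float(-(y * np.log(np.maximum(p, 1e-12))).sum())


def confusion_matrix(true_labels, predicted_labels, num_classes: int) -> np.ndarray:
    """K x K matrix with rows = true class, columns = predicted class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} true vs {p.shape} predicted")
    if t.size and (t.min() < 0 or t.max() >= num_classes
                   or p.min() < 0 or p.max() >= num_classes):
        raise ValueError(f"labels must lie in [0, {num_classes})")
    return _sk_confusion(t, p, labels=np.arange(num_classes))


@dataclass
class EvalReport:
    """Confusion matrix with per-class metrics; undefined cells are NaN."""

    matrix: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    accuracy: float

    def to_dict(self) -> dict:
        clean = lambda a: [None if np.isnan(v) else float(v) for v in a]
        return {
            "confusion_matrix": self.matrix.astype(int).tolist(),
            "precision": clean(self.precision),
            "recall": clean(self.recall),
            "specificity": clean(self.specificity),
            "accuracy": float(self.accuracy),
        }


def per_class_metrics(matrix) -> EvalReport:
    """Precision TP/(TP+FP), recall TP/(TP+FN), specificity TN/(TN+FP).

    Zero denominators yield NaN ("undefined"), never silently zero.
    """
    m = np.asarray(matrix, dtype=np.int64)
    total = m.sum()
    tp = np.diag(m).astype(float)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def safe(num, den):
        den = np.asarray(den, dtype=float)
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    accuracy = float(tp.sum() / total) if total else float("nan")
    return EvalReport(m, safe(tp, tp + fp), safe(tp, tp + fn), safe(tn, tn + fp),
                      accuracy)


def _batch_logits_loss(model: Module, xb: np.ndarray, yb: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of a batch, built on the autodiff graph."""
    logits = model(Tensor(xb))
    shift = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    log_z = shift.exp().sum(axis=1, keepdims=True).log()
    log_probs = shift - log_z
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(yb)), yb] = 1.0
    return -(Tensor(onehot) * log_probs).sum() * (1.0 / len(yb))


def recalibrate_bn(model: Module, images: np.ndarray, batch_size: int = 256) -> None:
    """Recompute batch-norm running statistics with frozen weights.

    With small mini-batches the exponential running averages can drift far
    from the statistics the trained weights actually produce; a single
    train-mode pass over the training images with exact moment accumulation
    closes that gap before evaluation.
    """
    from .nn import BatchNorm2d

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    model.train()
    for bn in bns:
        bn.start_stat_collection()
    for i in range(0, len(images), batch_size):
        model(Tensor(images[i : i + batch_size]))
    for bn in bns:
        bn.finish_stat_collection()
    model.eval()


def predict(model: Module, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Predicted class indices for an (N, C, H, W) image array."""
    model.eval()
    preds = []
    for i in range(0, len(images), batch_size):
        logits = model(Tensor(images[i : i + batch_size]))
        preds.append(logits.data.argmax(axis=1))
    return np.concatenate(preds)


def evaluate(model: Module, images: np.ndarray, labels: np.ndarray,
             num_classes: int | None = None, batch_size: int = 32) -> EvalReport:
    labels = np.asarray(labels)
    k = num_classes or int(labels.max()) + 1
    preds = predict(model, images, batch_size)
    return per_class_metrics(confusion_matrix(labels, preds, k))


def train(model: Module, train_data: tuple[np.ndarray, np.ndarray],
          cfg: TrainConfig, val_data: tuple[np.ndarray, np.ndarray] | None = None,
          verbose: bool = False) -> tuple[Module, dict]:
    """Train in place; returns the model and per-epoch loss/accuracy curves.

    Fully seeded: the shuffling order derives from ``cfg.seed`` alone, so two
    runs from identical initial weights produce identical curves.
    """
    x_train, y_train = train_data
    if len(x_train) == 0:
        raise ValueError("empty training set")
    y_train = np.asarray(y_train)
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    history: dict[str, list[float]] = {"train_loss": [], "train_accuracy": []}
    if val_data is not None:
        history["val_accuracy"] = []
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            loss = _batch_logits_loss(model, x_train[idx], y_train[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss {loss.data!r} at epoch {epoch + 1}, "
                    f"batch {i // cfg.batch_size + 1}; try a smaller learning rate"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["train_loss"].append(float(np.mean(losses)))
        if cfg.bn_recalibrate:
            recalibrate_bn(model, x_train)
        train_acc = float((predict(model, x_train, cfg.batch_size) == y_train).mean())
        history["train_accuracy"].append(train_acc)
        msg = (f"epoch {epoch + 1:3d}/{cfg.epochs}  "
               f"loss {history['train_loss'][-1]:.4f}  train acc {train_acc:.3f}")
        if val_data is not None:
            val_acc = float(
                (predict(model, val_data[0], cfg.batch_size) == np.asarray(val_data[1])).mean()
            )
            history["val_accuracy"].append(val_acc)
            msg += f"  val acc {val_acc:.3f}"
        if verbose:
            print(msg)
    return model, history


def run_kfold_cv(dataset: tuple[np.ndarray, np.ndarray], model_factory,
                 train_cfg: TrainConfig, verbose: bool = False
                 ) -> tuple[list[EvalReport], float]:
    """Stratified k-fold cross-validation with a fresh model per fold.

    ``model_factory(seed)`` must return a newly initialized model. Returns the
    per-fold evaluation reports on each held-out fold and their mean accuracy.
    """
    images, labels = dataset
    labels = np.asarray(labels)
    splitter = StratifiedKFold(n_splits=train_cfg.folds, shuffle=True,
                               random_state=train_cfg.seed)
    reports = []
    for fold, (tr_idx, va_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        model = model_factory(train_cfg.seed + fold)
        fold_cfg = TrainConfig(**{**train_cfg.__dict__, "seed": train_cfg.seed + fold})
        train(model, (images[tr_idx], labels[tr_idx]), fold_cfg,
              val_data=(images[va_idx], labels[va_idx]), verbose=verbose)
        reports.append(evaluate(model, images[va_idx], labels[va_idx],
                                num_classes=int(labels.max()) + 1,
                                batch_size=train_cfg.batch_size))
    mean_acc = float(np.mean([r.accuracy for r in reports]))
    return reports, mean_acc
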