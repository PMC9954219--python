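"""Training loop and the evaluation stack.

Training uses the reference hyperparameters: Adam at learning rate 5e-4,
batch size 16, at most 30 epochs, early stopping when the validation loss
stops improving (no improvement beyond 1e-4 for ``patience`` = 5
consecutive epochs), and a reduce-on-plateau learning-rate factor of 0.2.
A hard floor of 10 epochs applies before early stopping may trigger; a
plateau reached earlier reduces the learning rate instead.  The parameters
with the best validation loss are restored at the end.

Evaluation is per-class one-vs-rest on the 6x6 confusion matrix: accuracy,
recall (sensitivity), specificity, precision and F1 per class,

    A = (TP + TN) / (TP + FN + FP + TN)        R = TP / (TP + FN)
    S = TN / (FP + TN)                          P = TP / (TP + FP)
    F1 = 2 TP / (2 TP + FN + FP)

aggregated as support-weighted means, plus the overall accuracy
trace/total.  ROC curves are one-vs-rest per class; the single summary AUC
is micro-averaged over the flattened one-vs-rest problem (macro available).
Fold-wise results aggregate as mean and sample standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve

from .architectures import build_variant
from .data import FoldPlan, build_fold_plan
from .labels import CLASS_NAMES, ClassLabel
from .nn import Adam, Sequential, softmax_cross_entropy

__all__ = [
    "Hyperparams",
    "TrainingHistory",
    "PlateauPolicy",
    "DivergenceError",
    "train_model",
    "confusion_matrix",
    "ConfusionMatrix",
    "MetricsReport",
    "class_metrics",
    "misclassification_audit",
    "roc_auc",
    "cross_validate",
    "CrossValResult",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class Hyperparams:
    """Training hyperparameters; defaults are the reference settings."""

    learning_rate: float = 0.0005
    batch_size: int = 16
    max_epochs: int = 30
    patience: int = 5
    min_epochs: int = 10  # hard floor before early stopping may trigger
    lr_reduce_factor: float = 0.2
    min_delta: float = 1e-4  # below this, a loss change counts as "constant"
    q_order: int = 3
    seed: int = 0


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stop_reason: str = ""
    epochs_run: int = 0
    best_epoch: int = -1


class PlateauPolicy:
    """Early-stopping / reduce-on-plateau bookkeeping.

    Improvement means the monitored loss drops more than ``min_delta``
    below the best seen.  After ``patience`` consecutive non-improving
    epochs: stop if at least ``min_epochs`` epochs have run, otherwise
    multiply the learning rate by ``factor`` and keep going.
    """

    def __init__(self, patience=5, min_delta=1e-4, factor=0.2, min_epochs=10):
        self.patience = patience
        self.min_delta = min_delta
        self.factor = factor
        self.min_epochs = min_epochs
        self.best = math.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, loss: float):
        """Returns one of "continue", "improved", "reduce_lr", "stop"."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
            return "improved"
        self.stale += 1
        if self.stale >= self.patience:
            if epoch + 1 >= self.min_epochs:
                return "stop"
            self.stale = 0
            return "reduce_lr"
        return "continue"


def _evaluate(model, x, y, batch_size=64):
    total, correct, loss_sum = 0, 0, 0.0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = model.forward(xb)
        loss, _, probs = softmax_cross_entropy(logits, yb)
        loss_sum += loss * len(xb)
        correct += int(np.sum(probs.argmax(axis=1) == yb))
        total += len(xb)
    return loss_sum / total, correct / total


def train_model(model: Sequential, x_train, y_train, x_val, y_val,
                hp: Hyperparams | None = None, x_test=None, y_test=None,
                verbose=False, log=None):
    """Train with Adam, early stopping and reduce-on-plateau.

    Arrays are (N, C, H, W) inputs and integer label vectors.  Returns
    (model with best-validation parameters restored, TrainingHistory).
    """
    hp = hp or Hyperparams()
    if len(x_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(hp.seed)
    opt = Adam(model, lr=hp.learning_rate)
    policy = PlateauPolicy(hp.patience, hp.min_delta, hp.lr_reduce_factor, hp.min_epochs)
    hist = TrainingHistory()
    best_state = model.state_dict()
    n = len(x_train)
    for epoch in range(hp.max_epochs):
        order = rng.permutation(n)
        loss_sum, correct = 0.0, 0
        for i in range(0, n, hp.batch_size):
            idx = order[i : i + hp.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            model.zero_grad()
            logits = model.forward(xb)
            loss, grad, probs = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch + 1}")
            model.backward(grad)
            opt.step()
            loss_sum += loss * len(xb)
            correct += int(np.sum(probs.argmax(axis=1) == yb))
        val_loss, val_acc = _evaluate(model, x_val, y_val)
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch + 1}")
        hist.train_loss.append(loss_sum / n)
        hist.train_acc.append(correct / n)
        hist.val_loss.append(val_loss)
        hist.val_acc.append(val_acc)
        hist.lr.append(opt.lr)
        if x_test is not None:
            t_loss, t_acc = _evaluate(model, x_test, y_test)
            hist.test_loss.append(t_loss)
            hist.test_acc.append(t_acc)
        hist.epochs_run = epoch + 1
        msg = (f"epoch {epoch + 1:2d}  lr {opt.lr:.2e}  "
               f"train loss {hist.train_loss[-1]:.4f} acc {hist.train_acc[-1]:.3f}  "
               f"val loss {val_loss:.4f} acc {val_acc:.3f}")
        if log:
            log(msg)
        elif verbose:
            print(msg)
        action = policy.update(epoch, val_loss)
        if action == "improved":
            best_state = model.state_dict()
        elif action == "reduce_lr":
            opt.lr *= hp.lr_reduce_factor
        elif action == "stop":
            hist.stop_reason = "patience"
            break
    else:
        hist.stop_reason = "max_epochs"
    hist.best_epoch = policy.best_epoch
    model.load_state_dict(best_state)
    return model, hist


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """6x6 counts; rows are true classes, columns predicted, in label order."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=CLASS_NAMES, columns=CLASS_NAMES)


def confusion_matrix(y_true, y_pred, n_classes: int = 6) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


@dataclass
class MetricsReport:
    """Per-class and support-weighted one-vs-rest metrics."""

    per_class: pd.DataFrame  # rows: class names; columns: METRIC_NAMES + support
    weighted: dict[str, float]
    overall_accuracy: float

    def round_percent(self, metric: str, cls: str, ndigits: int = 2) -> float:
        """Percentage rounded half-up, the convention of printed tables."""
        v = float(self.per_class.loc[cls, metric]) * 100.0
        scale = 10**ndigits
        return math.floor(v * scale + 0.5) / scale


def class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest metrics per class with support-weighted aggregation.

    Classes with zero support are excluded from the weighted means (a
    warning is emitted) and their rows carry NaN.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = []
    for c, name in enumerate(CLASS_NAMES[: counts.shape[0]]):
        tp = counts[c, c]
        fn = counts[c].sum() - tp
        fp = counts[:, c].sum() - tp
        tn = total - tp - fn - fp
        support = tp + fn
        if support == 0:
            warnings.warn(f"class {name} has zero support; excluded from weighting")
            rows.append([name, *([np.nan] * 5), 0])
            continue
        acc = (tp + tn) / total
        rec = tp / (tp + fn)
        spec = tn / (fp + tn) if (fp + tn) else np.nan
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        f1 = 2 * tp / (2 * tp + fn + fp)
        rows.append([name, acc, prec, rec, spec, f1, support])
    frame = pd.DataFrame(
        rows, columns=["class", *METRIC_NAMES, "support"]
    ).set_index("class")
    valid = frame["support"] > 0
    w = frame.loc[valid, "support"]
    weighted = {
        m: float((frame.loc[valid, m] * w).sum() / w.sum()) for m in METRIC_NAMES
    }
    overall = float(np.trace(counts) / total)
    return MetricsReport(frame, weighted, overall)


def misclassification_audit(per_class_recalls, supports) -> int:
    """Total errors implied by printed per-class recall percentages.

    Per class: correct = round(recall/100 x support); errors are the
    remainder; returns the summed error count.
    """
    recalls = np.asarray(per_class_recalls, dtype=float)
    supports = np.asarray(supports, dtype=int)
    if np.any((recalls < 0) | (recalls > 100)):
        raise ValueError("recalls must be percentages in [0, 100]")
    correct = np.floor(recalls / 100.0 * supports + 0.5).astype(int)
    return int(np.sum(supports - correct))


def roc_auc(scores, y_true, average: str = "micro"):
    """One-vs-rest ROC curves per class plus a single summary AUC.

    scores: (n, n_classes) probability rows; returns (curves, auc) where
    curves maps class name -> (fpr, tpr, auc) and classes absent from the
    truth are flagged with None.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    n_classes = scores.shape[1]
    curves = {}
    aucs = []
    for c in range(n_classes):
        name = CLASS_NAMES[c] if c < len(CLASS_NAMES) else str(c)
        onehot = (y_true == c).astype(int)
        if onehot.sum() in (0, len(onehot)):
            warnings.warn(f"class {name} absent from truth; ROC undefined")
            curves[name] = None
            continue
        fpr, tpr, _ = _sk_roc_curve(onehot, scores[:, c])
        a = _sk_auc(fpr, tpr)
        curves[name] = (fpr, tpr, float(a))
        aucs.append((float(a), int(onehot.sum())))
    if average == "micro":
        onehot = np.zeros_like(scores, dtype=int)
        onehot[np.arange(len(y_true)), y_true] = 1
        fpr, tpr, _ = _sk_roc_curve(onehot.ravel(), scores.ravel())
        overall = float(_sk_auc(fpr, tpr))
    elif average == "macro":
        overall = float(np.mean([a for a, _ in aucs]))
    else:
        raise ValueError(f"unknown average {average!r}")
    return curves, overall


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CrossValResult:
    fold_reports: list[MetricsReport]
    fold_histories: list[TrainingHistory]
    fold_confusions: list[ConfusionMatrix]
    fold_scores: list[np.ndarray]
    fold_true: list[np.ndarray]
    plan: FoldPlan

    def summary(self) -> pd.DataFrame:
        """Mean and sample standard deviation of the weighted metrics."""
        table = pd.DataFrame(
            [
                {**r.weighted, "overall_accuracy": r.overall_accuracy}
                for r in self.fold_reports
            ]
        )
        return pd.DataFrame({"mean": table.mean(), "std": table.std(ddof=1)})


def cross_validate(x, y, model_name: str = "MBINet", hp: Hyperparams | None = None,
                   k: int = 5, input_size=None, q_order=None, seed=0,
                   augment=None, log=None, plan: FoldPlan | None = None):
    """Train one model per stratified fold and aggregate weighted metrics.

    x: (N, C, H, W) preprocessed images; y: integer labels.  ``augment``
    may be an AugmentationPolicy applied to the training split of each
    fold.  Per-fold failures propagate with the fold index attached.
    """
    hp = hp or Hyperparams()
    x = np.asarray(x)
    y = np.asarray(y, dtype=int)
    if input_size is None:
        input_size = (x.shape[2], x.shape[3], x.shape[1])
    if plan is None:
        plan = build_fold_plan(y, k=k, seed=seed)
    result = CrossValResult([], [], [], [], [], plan)
    for f, fold in enumerate(plan.folds):
        try:
            tr, va, te = fold["train"], fold["validation"], fold["test"]
            x_tr, y_tr = x[tr], y[tr]
            if augment is not None:
                # transforms run on the already-normalized arrays, so no
                # [0, 1] clipping here; exposed borders fill with 0
                aug_x, aug_y = [x_tr], [y_tr]
                for xi, yi in zip(x_tr, y_tr):
                    hwc = np.transpose(xi, (1, 2, 0)).astype(np.float64)
                    for tf in augment:
                        aug_x.append(np.transpose(tf.apply(hwc), (2, 0, 1))[None])
                        aug_y.append([yi])
                x_tr = np.concatenate(aug_x, axis=0).astype(x.dtype)
                y_tr = np.concatenate(aug_y, axis=0)
            model = build_variant(model_name, q_order=q_order,
                                  input_size=input_size, seed=hp.seed + f)
            fold_hp = Hyperparams(**{**hp.__dict__, "seed": hp.seed + f})
            model, hist = train_model(model, x_tr, y_tr, x[va], y[va],
                                      fold_hp, log=log)
            scores = model.predict_proba(x[te])
            preds = scores.argmax(axis=1)
            cm = confusion_matrix(y[te], preds)
            result.fold_reports.append(class_metrics(cm))
            result.fold_histories.append(hist)
            result.fold_confusions.append(cm)
            result.fold_scores.append(scores)
            result.fold_true.append(y[te])
        except Exception as e:
            raise type(e)(f"fold {f}: {e}") from e
    return result
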