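"""Training protocol, cross-validation, leave-one-donor-out, and metrics.

Training uses stochastic gradient descent with 0.90 Nesterov momentum, a
learning rate in [0.001, 0.01], 10-30 epochs, batch sizes of 32 or 64,
categorical cross-entropy (classification) or mean squared error
(regression), and an early-stopping rule: training ceases once the relative
training-loss improvement stays below a threshold (default 1e-3) for three
consecutive epochs.

Evaluation reports accuracy, macro-averaged precision/recall/F1 and a
row-normalized confusion matrix for classification; MAE/MSE/RMSE, Pearson r
(with p-value) and R^2 for regression.  Donor-level protocols aggregate
per-donor metrics as arithmetic mean and sample (n-1) standard deviation.
Statistics that are undefined on degenerate inputs (Pearson r under zero
variance, recall for an absent class) are reported as NaN with a warning,
never silently as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, r2_score

from .nn import Model, SGDNesterov, build_model, mse_loss, softmax_cross_entropy
from .nn.model import CnnSpec
from .tiling import TileDataset, augment_batch


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite during training."""


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Values outside the protocol ranges (lr in [0.001, 0.01], epochs in
    [10, 30], batch size in {32, 64}) are allowed but draw a warning.
    """

    learning_rate: float = 0.005
    epochs: int = 15
    batch_size: int = 32
    momentum: float = 0.90
    plateau_patience: int = 3
    plateau_min_rel_improvement: float = 1e-3
    seed: int = 0
    augment: bool = True

    def __post_init__(self) -> None:
        if not (0.001 <= self.learning_rate <= 0.01):
            warnings.warn(
                f"learning_rate {self.learning_rate} outside protocol range [0.001, 0.01]"
            )
        if not (10 <= self.epochs <= 30):
            warnings.warn(f"epochs {self.epochs} outside protocol range [10, 30]")
        if self.batch_size not in (32, 64):
            warnings.warn(f"batch_size {self.batch_size} outside protocol set {{32, 64}}")


@dataclass
class EvalReport:
    """Metrics of one evaluation; classification and regression fields."""

    task: str
    n_samples: int
    accuracy: float | None = None
    per_class_precision: list[float] | None = None
    per_class_recall: list[float] | None = None
    per_class_f1: list[float] | None = None
    precision: float | None = None  # macro
    recall: float | None = None
    f1: float | None = None
    confusion: list[list[float]] | None = None  # row-normalized
    confusion_counts: list[list[int]] | None = None
    mae: float | None = None
    mse: float | None = None
    rmse: float | None = None
    pearson_r: float | None = None
    pearson_p: float | None = None
    r2: float | None = None  # coefficient of determination
    r2_pearson: float | None = None  # squared Pearson correlation
    averaging: str = "macro"
    per_donor: dict | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def train(
    model: Model,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> dict:
    """Fit a model in place; returns the per-epoch history.

    ``x`` must already be normalized (NCHW float32); classification labels
    are integer class indices, regression targets are floats.  All shuffling
    and augmentation randomness derives from ``cfg.seed``, so a rebuilt model
    with the same seeds reproduces the history exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    regression = model.task == "regression"
    if regression:
        # Fit on standardized targets (the raw RS scale sits far from the
        # zero-initialized head); predictions are mapped back automatically.
        y = np.asarray(y, dtype=np.float32)
        model.target_mean = float(y.mean())
        model.target_std = float(y.std()) or 1.0
        y = (y - model.target_mean) / model.target_std
    opt = SGDNesterov(model.net.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    history: dict = {"train_loss": [], "train_accuracy": [], "val_accuracy": []}
    stall = 0
    prev_loss = None
    n = len(x)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = x[idx]
            if cfg.augment:
                xb = augment_batch(xb, rng)
            yb = y[idx]
            out = model.forward(xb, train=True)
            if regression:
                loss, dout = mse_loss(out, yb)
            else:
                loss, dout = softmax_cross_entropy(out, yb)
                correct += int((out.argmax(axis=1) == yb).sum())
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch + 1}; try a lower learning rate"
                )
            model.net.backward(dout)
            opt.step(model.net.gradients())
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        history["train_loss"].append(epoch_loss)
        history["train_accuracy"].append(None if regression else correct / n)
        if x_val is not None and not regression:
            val_acc = float((model.predict(x_val) == y_val).mean())
            history["val_accuracy"].append(val_acc)

        if prev_loss is not None:
            rel = (prev_loss - epoch_loss) / max(abs(prev_loss), 1e-12)
            stall = stall + 1 if rel < cfg.plateau_min_rel_improvement else 0
        prev_loss = epoch_loss
        if stall >= cfg.plateau_patience:
            break
    _recalibrate_batchnorm(model, x, rng)
    model.training_history = history
    return history


def _recalibrate_batchnorm(model: Model, x: np.ndarray, rng: np.random.Generator,
                           n_samples: int = 256) -> None:
    """Set batch-norm running statistics from one large training-data pass.

    Exponential running averages are poorly calibrated after short trainings;
    evaluation-mode predictions then disagree with training-mode behaviour.
    One forward pass with momentum 1 pins the running statistics to the
    statistics of an (up to ``n_samples``-tile) training sample.
    """
    from .nn.layers import BatchNorm

    idx = rng.permutation(len(x))[: min(n_samples, len(x))]
    bn_layers = [l for l in model.net.layers if isinstance(l, BatchNorm)]
    saved = [l.momentum for l in bn_layers]
    for layer in bn_layers:
        layer.momentum = 1.0
    try:
        model.forward(x[idx], train=True)
    finally:
        for layer, m in zip(bn_layers, saved):
            layer.momentum = m


def cross_validate(
    spec: CnnSpec,
    task: str,
    dataset: TileDataset,
    cfg: TrainConfig,
    folds: int | None = None,
) -> dict:
    """Five-fold cross-validation on the held-out validation pool.

    Each fold in turn is the validation set while the model trains on the
    remaining training tiles; per-fold and mean training/validation
    accuracies are returned.  A fresh model (seed derived from cfg.seed and
    the fold index) is built per fold.
    """
    folds = folds if folds is not None else dataset.n_folds
    fold_metrics = []
    for fold in range(folds):
        x_tr, y_tr = dataset.split_arrays("train", exclude_fold=fold)
        x_va, y_va = dataset.split_arrays("train", only_fold=fold)
        x_tr, x_va = dataset.normalize(x_tr), dataset.normalize(x_va)
        model = build_model(spec, task, seed=cfg.seed * 1009 + fold)
        fold_cfg = replace(cfg, seed=cfg.seed * 613 + fold)
        history = train(model, x_tr, y_tr, fold_cfg)
        val_acc = float((model.predict(x_va) == y_va).mean())
        fold_metrics.append(
            {
                "fold": fold,
                "train_accuracy": history["train_accuracy"][-1],
                "val_accuracy": val_acc,
            }
        )
    return {
        "folds": fold_metrics,
        "mean_train_accuracy": float(
            np.mean([m["train_accuracy"] for m in fold_metrics])
        ),
        "mean_val_accuracy": float(np.mean([m["val_accuracy"] for m in fold_metrics])),
    }


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def classification_report(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None
) -> EvalReport:
    """Accuracy, macro precision/recall/F1 and row-normalized confusion."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    labels = np.arange(n_classes)
    counts = confusion_matrix(y_true, y_pred, labels=labels)
    accuracy = float(np.trace(counts) / counts.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=np.nan
        )
    for name, arr in (("precision", prec), ("recall", rec), ("f1", f1)):
        if np.isnan(arr).any():
            warnings.warn(
                f"{name} undefined for classes {labels[np.isnan(arr)].tolist()} "
                "(no support or no predictions); reported as NaN"
            )
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        normalized = np.where(row_sums > 0, counts / row_sums, np.nan)
    return EvalReport(
        task="classification",
        n_samples=len(y_true),
        accuracy=accuracy,
        per_class_precision=[float(v) for v in prec],
        per_class_recall=[float(v) for v in rec],
        per_class_f1=[float(v) for v in f1],
        precision=float(np.nanmean(prec)),
        recall=float(np.nanmean(rec)),
        f1=float(np.nanmean(f1)),
        confusion=normalized.tolist(),
        confusion_counts=counts.tolist(),
    )


def regression_report(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """MAE, MSE, RMSE, Pearson r (+p), and both R^2 conventions."""
    y_true = np.asarray(y_true, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        warnings.warn("Pearson r undefined under zero variance; reported as NaN")
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(y_true, y_pred)
    r2 = float(r2_score(y_true, y_pred)) if np.std(y_true) > 0 else float("nan")
    return EvalReport(
        task="regression",
        n_samples=len(y_true),
        mae=mae,
        mse=mse,
        rmse=rmse,
        pearson_r=float(r),
        pearson_p=float(p),
        r2=r2,
        r2_pearson=float(r) ** 2 if np.isfinite(r) else float("nan"),
    )


def evaluate_classification(
    model: Model, x: np.ndarray, y: np.ndarray, n_classes: int | None = None
) -> EvalReport:
    pred = model.predict(x)
    report = classification_report(y, pred, n_classes=n_classes or model.head_size)
    report.task = model.task
    return report


def evaluate_regression(model: Model, x: np.ndarray, y: np.ndarray) -> EvalReport:
    pred = model.predict(x)
    report = regression_report(y, pred)
    report.task = model.task
    return report


def percentage_deviation(error: float, rs_range: tuple[float, float]) -> float:
    """Express an RS error as a percentage of the observed RS span (1 dp)."""
    lo, hi = rs_range
    if hi <= lo:
        raise ValueError(f"rs_range must satisfy hi > lo, got {rs_range}")
    if error < 0:
        raise ValueError("error must be non-negative")
    return round(100.0 * error / (hi - lo), 1)


def aggregate_metrics(
    per_donor: Mapping[str, Mapping[str, float]],
) -> tuple[dict[str, float], dict[str, float]]:
    """Arithmetic mean and sample (n-1) standard deviation across donors."""
    keys = sorted({k for metrics in per_donor.values() for k in metrics})
    means, sds = {}, {}
    for key in keys:
        values = np.array([metrics[key] for metrics in per_donor.values()], dtype=float)
        means[key] = float(values.mean())
        sds[key] = float(values.std(ddof=1)) if len(values) > 1 else float("nan")
    return means, sds


def leave_one_donor_out(
    data_by_donor: Mapping[str, tuple[np.ndarray, np.ndarray]],
    spec: CnnSpec,
    task: str,
    cfg: TrainConfig,
    normalize: Callable[[np.ndarray], np.ndarray] | None = None,
) -> dict:
    """Donor-generalization protocol: one trial per held-out donor.

    For each donor d the model trains on the pooled data of every other
    donor and is tested on donor d; per-donor reports plus mean +/- sample SD
    of accuracy/precision/recall/F1 are returned.
    """
    donors = sorted(data_by_donor)
    if len(donors) < 2:
        raise ValueError("leave-one-donor-out requires at least 2 donors")
    reports: dict[str, EvalReport] = {}
    for i, held_out in enumerate(donors):
        x_tr = np.concatenate([data_by_donor[d][0] for d in donors if d != held_out])
        y_tr = np.concatenate([data_by_donor[d][1] for d in donors if d != held_out])
        x_te, y_te = data_by_donor[held_out]
        if normalize is not None:
            x_tr, x_te = normalize(x_tr), normalize(x_te)
        model = build_model(spec, task, seed=cfg.seed * 2027 + i)
        train(model, x_tr, y_tr, replace(cfg, seed=cfg.seed * 431 + i))
        reports[held_out] = evaluate_classification(model, x_te, y_te)
    per_donor = {
        d: {"accuracy": r.accuracy, "precision": r.precision, "recall": r.recall, "f1": r.f1}
        for d, r in reports.items()
    }
    means, sds = aggregate_metrics(per_donor)
    return {"per_donor": reports, "mean": means, "sd": sds}
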