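"""Classification performance metrics and model comparison.

Metrics are computed from the 3 x 3 confusion matrix by one-vs-rest
reduction of each class c into TP/TN/FP/FN counts and the printed formulas

    accuracy_c  = [(TP/(TP+FN)) + (TN/(TN+FP))] * 0.5 * 100   (balanced accuracy)
    precision_c = TP/(TP+FP) * 100
    recall_c    = TP/(TP+FN) * 100
    f1_c        = 2 * precision_c * recall_c / (precision_c + recall_c)

aggregated as support-weighted means (so all four reported scores live on the
0-100 scale).  Weighted recall equals the plain fraction correct — an
algebraic identity that doubles as a self-check.  One-vs-rest ROC/AUC,
stratified k-fold cross-validation with per-fold refitting, and Tukey's
honest-significant-difference comparison of per-fold accuracies across models
complete the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold

from .models import TrainedModel, predict, predict_proba

__all__ = [
    "ConfusionMatrix", "MetricsReport", "CvResult",
    "confusion", "metrics", "roc_auc", "kfold_cv", "tukey_hsd",
]

N_CLASSES = 3


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = ground truth, cols = prediction

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_CLASSES, N_CLASSES) or (self.counts < 0).any():
            raise ValueError("counts must be a nonnegative 3 x 3 matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Row-normalized percentage view (rows sum to 100)."""
        rowsums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * self.counts / rowsums
        return np.where(rowsums > 0, out, 0.0)

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) counts for class ``c`` against the rest."""
        tp = int(self.counts[c, c])
        fn = int(self.counts[c].sum() - tp)
        fp = int(self.counts[:, c].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict[int, dict[str, float]]
    auc: dict[int, float] | None = None


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("need equal-length, non-empty label vectors")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reported as 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix, average: str = "weighted") -> MetricsReport:
    """Per-class one-vs-rest metrics and their support-weighted aggregates."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if average != "weighted":
        raise ValueError("only weighted averaging is supported")
    per_class: dict[int, dict[str, float]] = {}
    supports = cm.counts.sum(axis=1)
    for c in range(N_CLASSES):
        tp, tn, fp, fn = cm.one_vs_rest(c)
        sens = _safe_ratio(tp, tp + fn, f"recall of class {c}")
        spec = _safe_ratio(tn, tn + fp, f"specificity of class {c}")
        prec = _safe_ratio(tp, tp + fp, f"precision of class {c}")
        acc = (sens + spec) * 0.5 * 100
        prec *= 100
        rec = sens * 100
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class[c] = {"accuracy": acc, "precision": prec, "recall": rec,
                        "f1": f1, "support": int(supports[c])}
    w = supports / cm.total

    def agg(key: str) -> float:
        return float(sum(w[c] * per_class[c][key] for c in range(N_CLASSES)))

    return MetricsReport(accuracy=agg("accuracy"), precision=agg("precision"),
                         recall=agg("recall"), f1=agg("f1"), per_class=per_class)


def roc_auc(y_true: np.ndarray, probabilities: np.ndarray) -> dict[int, float | None]:
    """One-vs-rest trapezoidal AUC per class; None where the class is absent."""
    y_true = np.asarray(y_true, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    out: dict[int, float | None] = {}
    for c in range(probabilities.shape[1]):
        pos = y_true == c
        if pos.all() or not pos.any():
            out[c] = None
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), probabilities[:, c])
        out[c] = float(auc(fpr, tpr))
    return out


@dataclass
class CvResult:
    per_fold: list[MetricsReport]
    fold_accuracies: np.ndarray

    def summary(self) -> dict[str, tuple[float, float]]:
        """Mean and SD (ddof=1) per metric across folds."""
        out = {}
        for key in ("accuracy", "precision", "recall", "f1"):
            vals = np.array([getattr(r, key) for r in self.per_fold])
            out[key] = (float(vals.mean()), float(vals.std(ddof=1)))
        return out


def kfold_cv(model_factory, dataset, k: int = 10, seed: int = 42) -> CvResult:
    """Stratified k-fold CV, refitting ``model_factory(train_subset)`` per fold."""
    y = np.asarray(dataset.y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} samples; needs >= {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports, plain_accs = [], []
    for tr, te in skf.split(dataset.X, y):
        model = model_factory(dataset.subset(tr))
        y_pred = predict(model, dataset.X[te])
        reports.append(metrics(confusion(y[te], y_pred)))
        plain_accs.append(float((y_pred == y[te]).mean() * 100))
    return CvResult(per_fold=reports, fold_accuracies=np.array(plain_accs))


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.05):
    """Pairwise Tukey honest-significant-difference comparison.

    ``groups`` maps model name -> per-fold accuracies.  Returns a pandas
    DataFrame of pairwise mean differences, the confidence interval at the
    requested family-wise level, the p-value and a reject flag.
    """
    import pandas as pd

    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    res = stats.tukey_hsd(*arrays)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({
                "group1": names[i], "group2": names[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "ci_low": float(ci.low[i, j]), "ci_high": float(ci.high[i, j]),
                "pvalue": float(res.pvalue[i, j]),
                "reject": bool(res.pvalue[i, j] < alpha),
            })
    return pd.DataFrame(rows)
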