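"""Evaluation metrics: ACC, macro P/R/F1, macro MCC, micro/macro AUROC, micro AUPRC.

Macro averages are unweighted means over classes under the one-vs-rest
decomposition. MCC is computed per class in its binary form and
macro-averaged, with 0 substituted whenever a denominator factor vanishes.
Micro-averaged curve metrics flatten all (sample, class) one-vs-rest pairs
and compute a single curve; tied scores receive the Mann-Whitney half-credit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "confusion_counts",
    "accuracy",
    "macro_precision_recall",
    "macro_f1",
    "macro_mcc",
    "micro_auc",
    "macro_auc",
    "micro_auprc",
    "MetricsReport",
    "compute_report",
]


def _one_vs_rest(y: np.ndarray, n_classes: int) -> np.ndarray:
    """Binary indicator matrix (samples x classes) from labels or a 0/1 matrix."""
    y = np.asarray(y)
    if y.shape[0] == 0:
        raise ValueError("empty input")
    if y.ndim == 2:
        return y.astype(np.int64)
    out = np.zeros((y.shape[0], n_classes), dtype=np.int64)
    out[np.arange(y.shape[0]), y] = 1
    return out


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """One-vs-rest counts per class: array (n_classes, 4) of TP, FP, FN, TN."""
    t = _one_vs_rest(y_true, n_classes)
    p = _one_vs_rest(y_pred, n_classes)
    if t.shape[0] == 0:
        raise ValueError("empty input")
    tp = (t & p).sum(axis=0)
    fp = ((1 - t) & p).sum(axis=0)
    fn = (t & (1 - p)).sum(axis=0)
    tn = ((1 - t) & (1 - p)).sum(axis=0)
    return np.stack([tp, fp, fn, tn], axis=1)


def accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.ndim == 2:  # multi-label: exact-match ratio
        return float((y_true == y_pred).all(axis=1).mean())
    return float((y_true == y_pred).mean())


def macro_precision_recall(counts: np.ndarray) -> tuple[float, float]:
    tp, fp, fn, _ = counts.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    return float(prec.mean()), float(rec.mean())


def macro_f1(counts: np.ndarray) -> float:
    """Unweighted mean over classes of 2PR/(P+R); P+R = 0 contributes 0."""
    tp, fp, fn, _ = counts.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return float(f1.mean())


def macro_mcc(counts: np.ndarray) -> float:
    """Macro average of the per-class binary Matthews correlation coefficient."""
    tp, fp, fn, tn = counts.T.astype(float)
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(invalid="ignore", divide="ignore"):
        mcc = np.where(den > 0, num / np.sqrt(den), 0.0)
    return float(mcc.mean())


def micro_auc(scores: np.ndarray, y_true: np.ndarray) -> float:
    """AUROC over all flattened one-vs-rest (sample, class) pairs."""
    if np.asarray(y_true).shape[0] == 0:
        raise ValueError("empty input")
    t = _one_vs_rest(y_true, scores.shape[1]).ravel()
    if t.sum() == 0:
        raise ValueError("no positive labels")
    return float(roc_auc_score(t, np.asarray(scores).ravel()))


def macro_auc(scores: np.ndarray, y_true: np.ndarray) -> float:
    """Mean per-class AUROC; classes without positives (or negatives) skipped."""
    scores = np.asarray(scores)
    t = _one_vs_rest(y_true, scores.shape[1])
    aucs = []
    for i in range(scores.shape[1]):
        pos = t[:, i].sum()
        if pos == 0 or pos == t.shape[0]:
            continue
        aucs.append(roc_auc_score(t[:, i], scores[:, i]))
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


def micro_auprc(scores: np.ndarray, y_true: np.ndarray) -> float:
    """Area under the step-wise precision-recall curve on flattened pairs."""
    t = _one_vs_rest(y_true, np.asarray(scores).shape[1]).ravel()
    if t.sum() == 0:
        raise ValueError("no positive labels")
    return float(average_precision_score(t, np.asarray(scores).ravel()))


@dataclass
class MetricsReport:
    acc: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_mcc: float
    mi_auc: float
    ma_auc: float
    mi_auprc: float
    per_class_counts: list[list[int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_mcc": self.macro_mcc,
            "mi_auc": self.mi_auc,
            "ma_auc": self.ma_auc,
            "mi_auprc": self.mi_auprc,
            "per_class_counts": self.per_class_counts,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compute_report(scores: np.ndarray, y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Full metric suite from class scores, true labels and hard predictions."""
    scores = np.asarray(scores)
    counts = confusion_counts(y_true, y_pred, scores.shape[1])
    prec, rec = macro_precision_recall(counts)
    return MetricsReport(
        acc=accuracy(y_true, y_pred),
        macro_precision=prec,
        macro_recall=rec,
        macro_f1=macro_f1(counts),
        macro_mcc=macro_mcc(counts),
        mi_auc=micro_auc(scores, y_true),
        ma_auc=macro_auc(scores, y_true),
        mi_auprc=micro_auprc(scores, y_true),
        per_class_counts=counts.tolist(),
    )
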