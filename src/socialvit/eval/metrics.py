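"""Classification metrics: confusion matrix, per-class precision / recall /
F1 (harmonic mean), overall accuracy, and one-vs-rest ROC / AUC.

Zero-denominator precision or recall is defined as 0 (with a logged
warning).  Overall precision/recall/F1 are reported both macro-averaged and
support-weighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from ..model.network import CLASS_NAMES

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    counts: np.ndarray                  # (K, K) ints; rows true, columns predicted
    class_names: tuple[str, ...] = CLASS_NAMES

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out


def confusion(predictions, labels, n_classes: int = len(CLASS_NAMES)) -> ConfusionMatrix:
    predictions = np.asarray(predictions, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if predictions.shape != labels.shape:
        raise EvaluationError(
            f"{len(predictions)} predictions vs {len(labels)} labels"
        )
    if len(labels) and (labels.min() < 0 or labels.max() >= n_classes
                        or predictions.min() < 0 or predictions.max() >= n_classes):
        raise EvaluationError(f"class index outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (labels, predictions), 1)
    return ConfusionMatrix(counts, CLASS_NAMES[:n_classes] if n_classes <= 5 else
                           tuple(str(i) for i in range(n_classes)))


# ---------------------------------------------------------------------------
# precision / recall / F1 / accuracy
# ---------------------------------------------------------------------------

def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ClassMetrics:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    class_names: tuple[str, ...] = CLASS_NAMES
    macro: dict = field(default_factory=dict)
    weighted: dict = field(default_factory=dict)

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"precision": self.precision, "recall": self.recall,
             "f1": self.f1, "support": self.support},
            index=list(self.class_names),
        )


def per_class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    counts = cm.counts
    if counts.sum() == 0:
        raise EvaluationError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    for i in np.flatnonzero((tp + fp == 0) | (tp + fn == 0)):
        logger.warning("class %s has a zero denominator; metric set to 0",
                       cm.class_names[i])
    f1 = np.array([f1_from_precision_recall(p, r) for p, r in zip(precision, recall)])
    support = counts.sum(axis=1)
    accuracy = float(tp.sum() / counts.sum())
    share = support / support.sum()
    return ClassMetrics(
        precision=precision, recall=recall, f1=f1, support=support, accuracy=accuracy,
        class_names=cm.class_names,
        macro={"precision": float(precision.mean()), "recall": float(recall.mean()),
               "f1": float(f1.mean())},
        weighted={"precision": float(precision @ share), "recall": float(recall @ share),
                  "f1": float(f1 @ share)},
    )


# ---------------------------------------------------------------------------
# one-vs-rest ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    class_name: str


def auc_rank(scores: np.ndarray, positives: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties count one half)."""
    pos = scores[positives]
    neg = scores[~positives]
    if len(pos) == 0 or len(neg) == 0:
        raise EvaluationError("AUC undefined without both positives and negatives")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def roc_auc_ovr(scores: np.ndarray, labels: np.ndarray) -> dict[str, RocCurve | None]:
    """Per-class one-vs-rest ROC on softmax scores; missing classes -> None."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.ndim != 2 or len(scores) != len(labels):
        raise EvaluationError("scores must be (n, K) probability rows matching labels")
    out: dict[str, RocCurve | None] = {}
    for cls, name in enumerate(CLASS_NAMES[: scores.shape[1]]):
        positives = labels == cls
        if positives.all() or not positives.any():
            logger.warning("class %s absent on one side; AUC reported as missing", name)
            out[name] = None
            continue
        fpr, tpr, _ = _sk_roc_curve(positives.astype(int), scores[:, cls])
        auc = float(np.trapezoid(tpr, fpr))
        out[name] = RocCurve(fpr, tpr, auc, name)
    return out
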