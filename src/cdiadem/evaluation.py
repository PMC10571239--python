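"""Confusion-matrix metrics and ROC/AUC for the binary CN vs MCI/AD task.

The positive class is MCI/AD throughout.  ``metrics`` reports standard
precision TP/(TP+FP) as the headline value and specificity TN/(TN+FP)
separately: published write-ups of this metric family sometimes display the
specificity formula under the name "precision", so both quantities are
always emitted rather than silently choosing one.  Undefined metrics (zero
denominators) come back as NaN with a log line, never as a silent 0.

AUC is the normalized Mann-Whitney U statistic (rank-based, ties averaged),
which equals the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float = math.nan
    roc: np.ndarray | None = None  # ordered (FPR, TPR) pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["accuracy", "precision", "recall", "specificity", "f1", "auc"],
                "value": [self.accuracy, self.precision, self.recall,
                          self.specificity, self.f1, self.auc],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def confusion(labels, predictions) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with 1 = MCI/AD (positive), 0 = CN."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {predictions.shape}")
    if not (np.isin(labels, (0, 1)).all() and np.isin(predictions, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0 = CN, 1 = MCI/AD)")
    return ConfusionCounts(
        tp=int(((labels == 1) & (predictions == 1)).sum()),
        tn=int(((labels == 0) & (predictions == 0)).sum()),
        fp=int(((labels == 0) & (predictions == 1)).sum()),
        fn=int(((labels == 1) & (predictions == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined (zero denominator); reporting NaN", name)
        return math.nan
    return num / den


def metrics(counts: ConfusionCounts) -> EvalReport:
    """Scalar metrics from confusion counts.

    accuracy  = (TP+TN)/(TP+FN+TN+FP)
    recall    = TP/(TP+FN)          (sensitivity)
    precision = TP/(TP+FP)
    specificity = TN/(TN+FP)
    F1 = 2 * precision * recall / (precision + recall)
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    accuracy = _ratio(tp + tn, counts.n, "accuracy")
    recall = _ratio(tp, tp + fn, "recall")
    precision = _ratio(tp, tp + fp, "precision")
    specificity = _ratio(tn, tn + fp, "specificity")
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
        logger.warning("metric f1 undefined; reporting NaN")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalReport(accuracy=accuracy, precision=precision, recall=recall,
                      specificity=specificity, f1=f1)


def roc_auc(labels, scores) -> tuple[float, np.ndarray]:
    """AUC plus the ROC curve for positive-class scores.

    AUC is computed by rank-averaging (Mann-Whitney U / (n+ * n-)), so tied
    scores contribute 1/2 per discordant-tied pair.  The curve sweeps the
    unique scores as thresholds; it starts at (0, 0), ends at (1, 1) and is
    monotone in both coordinates.  Single-class input yields NaN.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        logger.warning("AUC undefined: only one class present; reporting NaN")
        return math.nan, np.array([[0.0, 0.0], [1.0, 1.0]])

    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # step curve: descending unique thresholds, cumulative TP/FP
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    last_of_threshold = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = tps[last_of_threshold] / n_pos
    fpr = fps[last_of_threshold] / n_neg
    roc = np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])
    return float(auc), roc


def evaluate(labels, scores, threshold: float = 0.5) -> EvalReport:
    """Full report: hard labels from score > threshold (tie -> CN), plus rank-based AUC."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    predictions = (scores > threshold).astype(int)
    report = metrics(confusion(labels, predictions))
    report.auc, report.roc = roc_auc(labels, scores)
    return report


def write_roc(roc: np.ndarray, path) -> None:
    pd.DataFrame(roc, columns=["fpr", "tpr"]).to_csv(path, sep="\t", index=False)
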