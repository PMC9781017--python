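"""Confusion-matrix metrics and exact ROC AUC.

ACC = (TP+TN)/total, TPR = TP/(TP+FN), TNR = TN/(TN+FP),
F1 = 2TP/(2TP+FP+FN); AUC is the Mann-Whitney statistic with midrank tie
handling (equivalent to trapezoidal ROC integration).  Undefined
denominators are reported as NaN, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class PerformanceReport:
    ACC: float
    TPR: float
    TNR: float
    F1: float
    ROC_AUC: float = float("nan")


def confusion(predictions, labels) -> ConfusionCounts:
    """2x2 counts from boolean predictions against boolean labels."""
    predictions = np.asarray(predictions, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels length mismatch")
    return ConfusionCounts(
        TP=int(np.sum(predictions & labels)),
        TN=int(np.sum(~predictions & ~labels)),
        FP=int(np.sum(predictions & ~labels)),
        FN=int(np.sum(~predictions & labels)),
    )


def report(counts: ConfusionCounts) -> PerformanceReport:
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return PerformanceReport(
        ACC=ratio(counts.TP + counts.TN, counts.total),
        TPR=ratio(counts.TP, counts.TP + counts.FN),
        TNR=ratio(counts.TN, counts.TN + counts.FP),
        F1=ratio(2 * counts.TP, 2 * counts.TP + counts.FP + counts.FN),
    )


def roc_auc(scores, labels) -> float:
    """Exact ROC AUC: Mann-Whitney U / (n_pos * n_neg) with midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)           # midranks
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
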