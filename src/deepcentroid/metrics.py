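"""Binary classification metrics: MCC, AUC, accuracy, F1.

MCC (Matthews correlation coefficient) is the primary metric throughout the
cascade — it drives base-classifier pruning and the layer-wise stopping rule —
because it stays informative under the class imbalance typical of omics
cohorts. Conventions: any zero factor in the MCC denominator yields 0; AUC is
the Mann–Whitney rank statistic with ties counted 1/2; F1 is reported for the
positive class.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from scipy.stats import rankdata


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, fp, tn, fn = counts
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return mcc(confusion(y_true, y_pred))


def accuracy(counts: ConfusionCounts) -> float:
    if counts.n == 0:
        raise ValueError("empty confusion table")
    return (counts.tp + counts.tn) / counts.n


def f1(counts: ConfusionCounts) -> float:
    """F1 of the positive class; 0 when precision+recall is degenerate."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 0.0
    return 2 * counts.tp / denom


def auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann–Whitney U statistic (midranks for ties)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have the same shape")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present in y_true")
    ranks = rankdata(scores)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
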