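"""Evaluation metrics for imbalanced binary peptide classification.

Threshold-dependent metrics come from the confusion matrix at a given
probability cutoff (predicted positive iff score >= threshold):

    sensitivity = TP / (TP + FN)                   (percent)
    specificity = TN / (TN + FP)                   (percent)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)  (percent)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A degenerate MCC denominator (any factor zero) is reported as 0, the
standard convention. AUCROC is threshold-independent and equals the
Mann-Whitney probability that a random positive outscores a random negative
(ties counting one half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Confusion counts with the >= threshold positive-call convention."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size == 0:
        raise ValueError("empty input")
    if s.shape != y.shape:
        raise ValueError("scores and labels length mismatch")
    pred = s >= threshold
    return ConfusionCounts(
        TP=int(np.count_nonzero(pred & (y == 1))),
        FP=int(np.count_nonzero(pred & (y == 0))),
        TN=int(np.count_nonzero(~pred & (y == 0))),
        FN=int(np.count_nonzero(~pred & (y == 1))),
    )


def binary_metrics(counts: ConfusionCounts) -> Dict[str, float]:
    """Sensitivity/specificity/accuracy (percent) and MCC from counts."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "mcc": mcc,
    }


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve in [0, 1]; requires both classes present."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class EvalReport:
    """The five benchmark metrics plus the confusion counts behind them."""

    sensitivity: float
    specificity: float
    accuracy: float
    aucroc: float
    mcc: float
    counts: ConfusionCounts
    split: str = "validation"

    @classmethod
    def from_scores(
        cls,
        scores: Sequence[float],
        labels: Sequence[int],
        threshold: float = 0.5,
        split: str = "validation",
    ) -> "EvalReport":
        counts = confusion_at_threshold(scores, labels, threshold)
        m = binary_metrics(counts)
        return cls(
            sensitivity=m["sensitivity"],
            specificity=m["specificity"],
            accuracy=m["accuracy"],
            aucroc=roc_auc(scores, labels),
            mcc=m["mcc"],
            counts=counts,
            split=split,
        )

    def as_dict(self) -> Dict[str, float]:
        return {
            "split": self.split,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "aucroc": self.aucroc,
            "mcc": self.mcc,
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "TN": self.counts.TN,
            "FN": self.counts.FN,
        }
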