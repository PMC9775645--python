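"""Binary-classification metrics: Acc, Sn, Sp, MCC and AUC.

Acc = (TP+TN)/(TP+TN+FP+FN);  Sn = TP/(TP+FN);  Sp = TN/(TN+FP);
MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TP+FP)(TN+FP)(TP+FN)).

AUC is computed by the rank (Mann-Whitney U) formulation with ties counted
one half; it equals trapezoidal integration of the ROC curve.  Conventions:
a score >= threshold predicts positive; MCC is 0 when any marginal in its
denominator is 0; sensitivity/specificity are 0 when their denominator is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("confusion counts are all zero")


@dataclass(frozen=True)
class EvalReport:
    counts: ConfusionCounts
    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {"TP": self.counts.TP, "TN": self.counts.TN,
                "FP": self.counts.FP, "FN": self.counts.FN,
                "Acc": self.acc, "Sn": self.sn, "Sp": self.sp,
                "MCC": self.mcc, "AUC": self.auc,
                "threshold": self.threshold}


def _check_inputs(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty score/label arrays")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts at a threshold (score == threshold predicts positive)."""
    scores, labels = _check_inputs(scores, labels)
    pred = scores >= threshold
    return ConfusionCounts(TP=int(np.sum(pred & (labels == 1))),
                           TN=int(np.sum(~pred & (labels == 0))),
                           FP=int(np.sum(pred & (labels == 0))),
                           FN=int(np.sum(~pred & (labels == 1))))


def accuracy(c: ConfusionCounts) -> float:
    return (c.TP + c.TN) / (c.TP + c.TN + c.FP + c.FN)


def sensitivity(c: ConfusionCounts) -> float:
    return c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0


def specificity(c: ConfusionCounts) -> float:
    return c.TN / (c.TN + c.FP) if c.TN + c.FP else 0.0


def mcc(c: ConfusionCounts) -> float:
    denom = ((c.TN + c.FN) * (c.TP + c.FP) * (c.TN + c.FP) * (c.TP + c.FN))
    if denom == 0:
        return 0.0
    return float((c.TP * c.TN - c.FP * c.FN) / np.sqrt(float(denom)))


def auc(scores, labels) -> float:
    """Area under the ROC curve via the normalised Mann-Whitney U statistic
    (tied score pairs count one half)."""
    scores, labels = _check_inputs(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)           # midranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve as an array of (FPR, TPR, threshold) rows."""
    scores, labels = _check_inputs(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr, thr])


def write_roc_tsv(scores, labels, path) -> None:
    pts = roc_points(scores, labels)
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\tthreshold\n")
        for fp, tp, th in pts:
            fh.write(f"{fp:.10g}\t{tp:.10g}\t{th:.10g}\n")


def evaluate(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Full evaluation report for one run."""
    c = confusion(scores, labels, threshold)
    return EvalReport(c, accuracy(c), sensitivity(c), specificity(c),
                      mcc(c), auc(scores, labels), threshold)
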