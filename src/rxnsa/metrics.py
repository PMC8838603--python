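"""Binary classification metrics: ACC, MCC and ROC-AUC.

The positive class is ES throughout: TP counts true ES, TN true HS.
MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP)), defined as 0
when any factor of the denominator vanishes. ROC-AUC is computed from the
Mann-Whitney rank statistic with ties counted half.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .curation import ES, HS


@dataclass(frozen=True)
class EvalReport:
    acc: float
    mcc: float
    auc: float | None
    confusion: tuple  # (TP, TN, FP, FN)


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    return (tp + tn) / total


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    if denom == 0:
        return 0.0
    return (tp * tn - fn * fp) / math.sqrt(denom)


def roc_auc(scores, positives) -> float:
    """AUC via midranks: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    n_pos = int(positives.sum())
    n_neg = int((~positives).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[positives].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Score a classifier's ES-probabilities against ES/HS labels.

    ACC and MCC use the confusion matrix at ``threshold``; AUC is
    threshold-free and reported as ``None`` when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    if len(scores) != len(labels) or len(labels) == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    bad = {l for l in labels} - {ES, HS}
    if bad:
        raise ValueError(f"unknown labels: {bad}")
    positives = np.array([l == ES for l in labels], dtype=bool)
    predicted = scores >= threshold
    tp = int(np.sum(predicted & positives))
    tn = int(np.sum(~predicted & ~positives))
    fp = int(np.sum(predicted & ~positives))
    fn = int(np.sum(~predicted & positives))
    try:
        auc = roc_auc(scores, positives)
    except ValueError:
        auc = None
    return EvalReport(acc=accuracy(tp, tn, fp, fn), mcc=mcc(tp, tn, fp, fn),
                      auc=auc, confusion=(tp, tn, fp, fn))
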