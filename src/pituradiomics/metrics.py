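"""ROC analysis, optimal cutoff, and confusion summaries for the SVM score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RocResult:
    points: pd.DataFrame   # threshold, sensitivity, specificity, fpr
    auc: float
    cutoff: float          # Youden-J maximizer; ties -> higher specificity


@dataclass
class ConfusionSummary:
    """Counts and accuracy of a thresholded score, Table-3 style."""

    tp: int
    tn: int
    fp: int
    fn: int
    cutoff: float
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int,
                    cutoff: float = 0.0, auc: float | None = None) -> "ConfusionSummary":
        return cls(int(tp), int(tn), int(fp), int(fn), float(cutoff), auc)


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    return s, y


def roc_analysis(scores, labels) -> RocResult:
    """Full ROC curve, trapezoid AUC, and Youden-optimal cutoff.

    The prediction rule is positive iff score ≥ cutoff. AUC computed by the
    trapezoid over all distinct thresholds equals the normalized
    Mann-Whitney U statistic (ties counted half). Among cutoffs maximizing
    Youden's J = sensitivity + specificity − 1, the largest (most specific)
    is returned.
    """
    s, y = _check_scores_labels(scores, labels)
    n1, n0 = int(y.sum()), int((y == 0).sum())
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    tp = np.array([(s[y == 1] >= t).sum() for t in thresholds], dtype=float)
    fp = np.array([(s[y == 0] >= t).sum() for t in thresholds], dtype=float)
    sens = tp / n1
    fpr = fp / n0
    auc = float(np.trapezoid(sens, fpr))
    j = sens - fpr
    best = j == j.max()
    # ties -> higher specificity = lower fpr = higher threshold = earliest index
    k = int(np.argmax(best))
    cutoff = float(thresholds[k]) if np.isfinite(thresholds[k]) else float(np.unique(s)[-1] + 1)
    points = pd.DataFrame({
        "threshold": thresholds,
        "sensitivity": sens,
        "specificity": 1.0 - fpr,
        "fpr": fpr,
    })
    return RocResult(points, auc, cutoff)


def confusion(scores, labels, cutoff: float) -> ConfusionSummary:
    """Confusion counts of the rule ``predict positive iff score ≥ cutoff``."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    s, y = _check_scores_labels(scores, labels)
    pred = s >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return ConfusionSummary(tp, tn, fp, fn, float(cutoff),
                            auc=roc_analysis(s, y).auc)


def scores_from_counts(tp: int, tn: int, fp: int, fn: int):
    """Synthesize (scores, labels) realizing given confusion counts at cutoff 0.5.

    Useful for passing printed count tables through :func:`confusion`.
    """
    scores = np.concatenate([np.ones(tp + fp), np.zeros(tn + fn)])
    labels = np.concatenate([np.ones(tp), np.zeros(fp), np.zeros(tn), np.ones(fn)])
    return scores, labels.astype(int)
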