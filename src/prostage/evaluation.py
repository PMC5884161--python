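"""Confusion-matrix metrics, ROC curves and AUC with Hanley-McNeil error.

NOCD (extraprostatic disease) is the positive class throughout: sensitivity
is the fraction of NOCD cases called NOCD, specificity the fraction of OCD
cases called OCD.  The ROC score for the fused classifier is the combined
mass on {NOCD}; a case is called positive when its score is >= the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Label

__all__ = [
    "ConfusionMatrix",
    "RocPoint",
    "AucEstimate",
    "EvalRow",
    "EvalReport",
    "UndefinedMetricError",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "roc_curve",
    "auc_with_ci",
    "evaluate_scores",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for this confusion matrix."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with NOCD positive: tp = NOCD called NOCD, tn = OCD called OCD."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    fpr: float
    tpr: float


@dataclass(frozen=True)
class AucEstimate:
    """Trapezoidal AUC with Hanley-McNeil SE and a Wald 95% CI."""

    auc: float
    se: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0 and self.se >= 0.0):
            raise ValueError("invalid AUC estimate")
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must bracket the AUC")


def confusion(true_labels: Sequence[Label], predicted: Sequence[Label]) -> ConfusionMatrix:
    if len(true_labels) != len(predicted) or len(true_labels) == 0:
        raise ValueError("label sequences must be non-empty and of equal length")
    tp = fn = tn = fp = 0
    for t, p in zip(true_labels, predicted):
        if t == Label.NOCD:
            if p == Label.NOCD:
                tp += 1
            else:
                fn += 1
        else:
            if p == Label.OCD:
                tn += 1
            else:
                fp += 1
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def sensitivity(cm: ConfusionMatrix) -> float:
    """tp / (tp + fn): probability of correctly calling NOCD."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("no NOCD cases: sensitivity undefined")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """tn / (tn + fp): probability of correctly calling OCD."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("no OCD cases: specificity undefined")
    return cm.tn / (cm.tn + cm.fp)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def roc_curve(scores: Sequence[float], true_labels: Sequence[Label]) -> list[RocPoint]:
    """ROC points from sweeping thresholds over the distinct score values.

    A case is called NOCD when ``score >= threshold``.  The sweep runs from
    above the maximum score (nothing positive, the (0, 0) endpoint) down to
    the minimum score; the (1, 1) endpoint is appended if ties at the
    minimum leave it unreached.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.array([1 if l == Label.NOCD else 0 for l in true_labels])
    if len(scores) != len(y):
        raise ValueError("scores and labels must have equal length")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis needs at least one case of each class")

    points = [RocPoint(threshold=np.inf, fpr=0.0, tpr=0.0)]
    for t in np.unique(scores)[::-1]:
        called = scores >= t
        tp = int((called & (y == 1)).sum())
        fp = int((called & (y == 0)).sum())
        points.append(RocPoint(threshold=float(t), fpr=fp / n_neg, tpr=tp / n_pos))
    last = points[-1]
    if (last.fpr, last.tpr) != (1.0, 1.0):
        points.append(RocPoint(threshold=-np.inf, fpr=1.0, tpr=1.0))
    return points


def auc_with_ci(points: Sequence[RocPoint], n_pos: int, n_neg: int) -> AucEstimate:
    """Trapezoidal AUC with the Hanley-McNeil (1982) standard error.

    The trapezoidal area over threshold-swept points equals the tie-corrected
    rank statistic P(score_pos > score_neg) + 0.5 P(tie).  The 95% CI is
    ``auc +- 1.96 se`` clipped to [0, 1].
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes must be represented")
    fpr = np.array([p.fpr for p in points])
    tpr = np.array([p.tpr for p in points])
    order = np.argsort(fpr, kind="stable")
    fpr, tpr = fpr[order], tpr[order]
    if len(fpr) < 2:
        raise ValueError("degenerate ROC curve")
    auc = float(np.trapezoid(tpr, fpr))
    auc = min(max(auc, 0.0), 1.0)

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    return AucEstimate(
        auc=auc,
        se=se,
        ci_low=max(auc - 1.96 * se, 0.0),
        ci_high=min(auc + 1.96 * se, 1.0),
    )


@dataclass(frozen=True)
class EvalRow:
    """One classifier's metrics on one split."""

    classifier: str
    split: str
    cm: ConfusionMatrix
    sensitivity: float
    specificity: float
    accuracy: float
    auc: AucEstimate


@dataclass(frozen=True)
class EvalReport:
    """A stack of per-classifier evaluation rows, exportable as CSV or text."""

    rows: tuple[EvalRow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "classifier": r.classifier,
                "split": r.split,
                "tp": r.cm.tp,
                "fn": r.cm.fn,
                "tn": r.cm.tn,
                "fp": r.cm.fp,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "accuracy": r.accuracy,
                "auc": r.auc.auc,
                "se": r.auc.se,
                "ci_low": r.auc.ci_low,
                "ci_high": r.auc.ci_high,
            }
            for r in self.rows
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __str__(self) -> str:
        lines = [
            f"{'classifier':<40} {'split':<12} {'sens':>7} {'spec':>7} {'acc':>7} "
            f"{'AUC':>6} {'SE':>6} {'95% CI':>16}"
        ]
        for r in self.rows:
            lines.append(
                f"{r.classifier:<40} {r.split:<12} "
                f"{100 * r.sensitivity:6.2f}% {100 * r.specificity:6.2f}% {100 * r.accuracy:6.2f}% "
                f"{r.auc.auc:6.3f} {r.auc.se:6.3f} [{r.auc.ci_low:.3f}, {r.auc.ci_high:.3f}]"
            )
        return "\n".join(lines)


def evaluate_scores(
    classifier: str,
    split: str,
    true_labels: Sequence[Label],
    scores: Sequence[float],
    decisions: Sequence[Label],
) -> EvalRow:
    """Metrics for one classifier: decisions feed the confusion matrix, the
    continuous NOCD score feeds the ROC curve."""
    cm = confusion(true_labels, decisions)
    n_pos = sum(1 for l in true_labels if l == Label.NOCD)
    n_neg = len(true_labels) - n_pos
    points = roc_curve(scores, true_labels)
    return EvalRow(
        classifier=classifier,
        split=split,
        cm=cm,
        sensitivity=sensitivity(cm),
        specificity=specificity(cm),
        accuracy=accuracy(cm),
        auc=auc_with_ci(points, n_pos, n_neg),
    )
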