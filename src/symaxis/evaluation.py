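"""Scoring detector verdicts against ground truth.

Sensitivity is the percentage of truly symmetric cases reported symmetric,
specificity the percentage of truly asymmetric cases reported asymmetric;
both are left absent (``None``) when their denominator is zero.  The ROC is
traced by re-thresholding the stored vote tables over the verdict floor, so
no re-detection is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import DetectionReport
from .errors import InvalidInputError

__all__ = ["ConfusionMatrix", "EvalReport", "axis_error", "score", "roc_sweep", "auc"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be >= 0")

    @property
    def sensitivity(self) -> float | None:
        """100 * tp / (tp + fn), or None when there are no positive cases."""
        denom = self.tp + self.fn
        return None if denom == 0 else 100.0 * self.tp / denom

    @property
    def specificity(self) -> float | None:
        """100 * tn / (tn + fp), or None when there are no negative cases."""
        denom = self.tn + self.fp
        return None if denom == 0 else 100.0 * self.tn / denom


@dataclass
class EvalReport:
    matrix: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    mean_axis_error: float | None
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "matrix": {
                "tp": self.matrix.tp,
                "fn": self.matrix.fn,
                "fp": self.matrix.fp,
                "tn": self.matrix.tn,
            },
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mean_axis_error": self.mean_axis_error,
            "roc_points": [list(p) for p in self.roc_points],
        }


def axis_error(estimated: float, true: float) -> float:
    """Angular distance between two undirected axes, in ``[0, 90]``."""
    d = abs(estimated - true) % 180.0
    return min(d, 180.0 - d)


def _is_positive_verdict(report: DetectionReport) -> bool:
    return report.verdict == "symmetric"


def score(
    verdicts: list[tuple[DetectionReport, dict]],
    roc_thresholds: list[int] | None = None,
) -> EvalReport:
    """Confusion matrix, rates and mean axis error for labelled verdicts.

    Each ground-truth record needs a boolean ``symmetric`` key and, for
    symmetric cases, ``true_alpha``.  Axis error is averaged over true
    positives where both truth and verdict carry an axis.
    """
    if not verdicts:
        raise InvalidInputError("score requires at least one verdict")
    tp = fn = fp = tn = 0
    errors = []
    for report, truth in verdicts:
        truly_symmetric = bool(truth["symmetric"])
        positive = _is_positive_verdict(report)
        if truly_symmetric and positive:
            tp += 1
            if report.best_alpha is not None and truth.get("true_alpha") is not None:
                errors.append(axis_error(report.best_alpha, truth["true_alpha"]))
        elif truly_symmetric:
            fn += 1
        elif positive:
            fp += 1
        else:
            tn += 1
    matrix = ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
    roc = roc_sweep(verdicts, roc_thresholds) if roc_thresholds is not None else []
    return EvalReport(
        matrix=matrix,
        sensitivity=matrix.sensitivity,
        specificity=matrix.specificity,
        mean_axis_error=float(np.mean(errors)) if errors else None,
        roc_points=roc,
    )


def _max_votes(report: DetectionReport) -> int:
    if report.vote_table:
        return max(v for _, v in report.vote_table)
    return 0


def roc_sweep(
    reports: list[tuple[DetectionReport, dict]],
    thresholds: list[int],
) -> list[tuple[float, float]]:
    """One (FPR, TPR) point per vote threshold, re-using stored vote tables.

    A case counts positive at threshold ``m`` when its best candidate holds
    at least ``m`` votes (undetermined cases never count positive).  Both
    rates are non-increasing in the threshold.
    """
    points = []
    for m in thresholds:
        tp = fn = fp = tn = 0
        for report, truth in reports:
            positive = (
                report.verdict != "undetermined" and _max_votes(report) >= m
            )
            if truth["symmetric"]:
                tp += positive
                fn += not positive
            else:
                fp += positive
                tn += not positive
        tpr = tp / (tp + fn) if (tp + fn) else 0.0
        fpr = fp / (fp + tn) if (fp + tn) else 0.0
        points.append((float(fpr), float(tpr)))
    return points


def auc(roc_points: list[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC traced over thresholds, anchored at
    (0,0) and (1,1)."""
    pts = sorted(set(roc_points) | {(0.0, 0.0), (1.0, 1.0)})
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return float(np.trapezoid(ys, xs))
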