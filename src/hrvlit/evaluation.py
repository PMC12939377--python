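"""Diagnostic evaluation: confusion matrix, accuracy/sensitivity/specificity,
ROC curves over the decision threshold, AUC, and grouped evaluation.

Metrics are computed in full precision and rendered half-up to one decimal
percent for reporting.  Undefined metrics (zero denominator) are surfaced as
NaN, never silently zero.  The AUC equals the probability that a randomly
chosen event subject is ranked as higher-risk than a randomly chosen
non-event subject (pairwise concordance), which the trapezoidal integral of
the full threshold sweep reproduces exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .stratification import ReferenceStats, predict, stratify


class UndefinedAUCError(ValueError):
    """Raised when truths contain a single class, so the ROC is undefined."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ROCCurve:
    """(FPR, TPR) points sorted by FPR, with the threshold that produced each."""

    points: list[tuple[float, float]]
    thresholds: list[float]
    auc: float


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (82.45 -> 82.5), matching report conventions."""
    if not math.isfinite(value):
        return value
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def confusion(predictions, truths) -> ConfusionMatrix:
    """Four-cell tally of boolean predictions against boolean truths."""
    pred = np.asarray(predictions, dtype=bool)
    truth = np.asarray(truths, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("predictions and truths differ in length")
    return ConfusionMatrix(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
    )


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity in percent (full precision).

    accuracy = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

    A metric with a zero denominator is NaN (undefined).
    """
    acc = 100.0 * (cm.tp + cm.tn) / cm.n if cm.n else math.nan
    sens = 100.0 * cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else math.nan
    spec = 100.0 * cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else math.nan
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


def metrics_rounded(cm: ConfusionMatrix) -> dict[str, float]:
    """Metrics rendered half-up to one decimal percent."""
    return {k: round_half_up(v, 1) for k, v in metrics(cm).items()}


def _risk_scores(values: np.ndarray, direction: str) -> np.ndarray:
    """Higher score = more event-like, per the literature risk direction."""
    if direction == "negative":
        return -values
    if direction == "positive":
        return values.copy()
    raise ValueError(f"unknown direction {direction!r}")


def roc_curve(
    feature_values,
    truths,
    direction: str = "negative",
    k_grid: np.ndarray | None = None,
    ref: ReferenceStats | None = None,
) -> ROCCurve:
    """ROC of the stratification rule as its decision threshold varies.

    By default the raw feature threshold is swept continuously (every distinct
    value is a cut point), which is the limit of a dense sigma-multiplier
    grid.  Passing ``k_grid`` together with ``ref`` instead evaluates the
    literal ±k·SD rule at each grid value (a coarse staircase).
    """
    values = np.asarray(feature_values, dtype=float)
    truth = np.asarray(truths, dtype=bool)
    if values.shape != truth.shape:
        raise ValueError("feature values and truths differ in length")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("single-class truth vector; AUC undefined")

    if k_grid is not None:
        if ref is None:
            raise ValueError("k_grid sweep requires reference stats")
        pts: list[tuple[float, float]] = [(0.0, 0.0)]
        thresholds: list[float] = [math.inf]
        for k in sorted(np.asarray(k_grid, dtype=float), reverse=True):
            preds = np.array(
                [predict(stratify(v, ref, k), direction) for v in values]
            )
            cm = confusion(preds, truth)
            pts.append((cm.fp / n_neg, cm.tp / n_pos))
            thresholds.append(float(k))
        pts.append((1.0, 1.0))
        thresholds.append(-math.inf)
    else:
        scores = _risk_scores(values, direction)
        order = np.argsort(-scores, kind="stable")
        sorted_scores = scores[order]
        sorted_truth = truth[order]
        tps = np.cumsum(sorted_truth)
        fps = np.cumsum(~sorted_truth)
        # keep only the last index of each distinct score (ties move together)
        distinct = np.nonzero(np.r_[np.diff(sorted_scores) != 0, True])[0]
        pts = [(0.0, 0.0)] + [
            (fps[i] / n_neg, tps[i] / n_pos) for i in distinct
        ]
        thresholds = [math.inf] + [float(sorted_scores[i]) for i in distinct]

    pts_arr = sorted(set(pts))
    if pts_arr[-1] != (1.0, 1.0):
        pts_arr.append((1.0, 1.0))
    area = auc_from_points(pts_arr)
    return ROCCurve(points=pts_arr, thresholds=thresholds, auc=area)


def auc_from_points(points: list[tuple[float, float]]) -> float:
    """Trapezoidal area under FPR-sorted ROC points."""
    if len(points) < 2:
        raise ValueError("need at least 2 ROC points")
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    if np.any(np.diff(fpr) < 0):
        raise ValueError("ROC points must be sorted by FPR")
    return float(np.trapezoid(tpr, fpr))


def auc(roc: ROCCurve) -> float:
    return auc_from_points(roc.points)


def evaluate_by_group(
    cohort: pd.DataFrame,
    predictions: pd.DataFrame,
    group_field: str | None = None,
) -> pd.DataFrame:
    """Confusion cells plus metrics per group and overall.

    ``predictions`` must carry subject_id and prediction columns; truths and
    the grouping column come from the cohort.  Groups without events report
    NaN sensitivity.
    """
    merged = predictions.merge(
        cohort[[c for c in cohort.columns if c != "prediction"]],
        on="subject_id",
        suffixes=("", "_cohort"),
    )
    truth_col = "event" if "event" in predictions.columns else "event_cohort"
    rows = []

    def _row(label: str, frame: pd.DataFrame) -> dict:
        cm = confusion(frame["prediction"], frame[truth_col])
        out = {"group": label, "n": cm.n,
               "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
        out.update(metrics(cm))
        return out

    rows.append(_row("overall", merged))
    if group_field is not None:
        if group_field not in merged.columns:
            raise KeyError(f"no grouping column {group_field!r}")
        for value, frame in merged.groupby(group_field, sort=True):
            rows.append(_row(str(value), frame))
    return pd.DataFrame(rows)
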