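"""Evaluation metrics for slide-level binary classification.

AUC, classification error, recall, precision, specificity, balanced
accuracy and F1, plus mean +/- std aggregation over repeated runs.
Thresholded metrics predict positive iff the score strictly exceeds 0.5.
Degenerate denominators (no predicted/true positives) yield 0 rather
than NaN so aggregation over runs stays well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "compute_metrics",
    "auc",
    "report_from_scores",
    "aggregate_runs",
]

METRIC_FIELDS = ("auc", "error", "recall", "precision", "specificity", "bacc", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Bag-classification metrics, optionally aggregated over runs.

    For an aggregated report each metric field holds the across-run mean
    and ``std`` holds the per-metric sample standard deviation (ddof=1).
    """

    auc: float = float("nan")
    error: float = float("nan")
    recall: float = float("nan")
    precision: float = float("nan")
    specificity: float = float("nan")
    bacc: float = float("nan")
    f1: float = float("nan")
    n_runs: int = 1
    std: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in METRIC_FIELDS}
        d["n_runs"] = self.n_runs
        for k, s in self.std.items():
            d[f"{k}_std"] = s
        return d


def confusion(
    y_true: Sequence[int], y_prob: Sequence[float], threshold: float = 0.5
) -> ConfusionCounts:
    """Tally the confusion table; predict positive iff prob > threshold."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_prob, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_prob must have equal length")
    if yt.size == 0:
        raise ValueError("cannot tally an empty sample")
    pred = yp > threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (yt == 1))),
        tn=int(np.sum(~pred & (yt == 0))),
        fp=int(np.sum(pred & (yt == 0))),
        fn=int(np.sum(~pred & (yt == 1))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """All thresholded metrics from a confusion table (AUC excluded)."""
    if counts.total == 0:
        raise ValueError("confusion table is empty")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    recall = _safe_div(tp, tp + fn)
    precision = _safe_div(tp, tp + fp)
    specificity = 1.0 - _safe_div(fp, fp + tn) if (fp + tn) > 0 else 0.0
    bacc = (recall + specificity) / 2.0
    f1 = _safe_div(2.0 * precision * recall, precision + recall)
    error = 1.0 - (tp + tn) / counts.total
    return MetricsReport(
        error=error, recall=recall, precision=precision,
        specificity=specificity, bacc=bacc, f1=f1,
    )


def auc(y_true: Sequence[int], y_scores: Sequence[float]) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney probability that a random positive outscores a
    random negative, with ties counted half.  Undefined (raises) when only
    one class is present.
    """
    yt = np.asarray(y_true).astype(int)
    ys = np.asarray(y_scores, dtype=float)
    if yt.min() == yt.max():
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(yt, ys))


def report_from_scores(
    y_true: Sequence[int], y_prob: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """Full report (AUC + thresholded metrics) from probabilities."""
    rep = compute_metrics(confusion(y_true, y_prob, threshold))
    rep.auc = auc(y_true, y_prob)
    return rep


def aggregate_runs(reports: Sequence[MetricsReport], ddof: int = 1) -> MetricsReport:
    """Per-metric mean and sample std (ddof=1) across repeated runs."""
    if len(reports) == 0:
        raise ValueError("no reports to aggregate")
    agg = MetricsReport(n_runs=len(reports))
    for k in METRIC_FIELDS:
        vals = np.array([getattr(r, k) for r in reports], dtype=float)
        setattr(agg, k, float(vals.mean()))
        agg.std[k] = float(vals.std(ddof=ddof)) if len(vals) > ddof else 0.0
    return agg
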