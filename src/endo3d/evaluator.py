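"""Video-level prediction and evaluation.

A video's prediction aggregates up to ten randomly chosen segments: the
model's logits are converted to class probabilities and averaged across
segments; the video score is the mean positive-class ("upper") probability
and the predicted label the argmax of the mean probabilities (ties go to
the positive class).

Metrics follow the standard confusion-matrix definitions

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

computed for the positive (upper, minority) class, plus trapezoidal ROC
AUC. Ratios with a zero denominator are reported as 0 and flagged rather
than raised, so multi-run aggregation never aborts.

The attention ablation is judged with a paired two-sided t-test and a
Wilcoxon signed-rank test on per-run accuracies (pairs matched by run
seed). The signed-rank null is exact (rank-sum distribution by dynamic
programming, mid-rank ties, zero differences dropped) up to n = 25 pairs
and a continuity-corrected normal approximation beyond.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import nn
from .segmenter import (
    CLASS_TO_INDEX,
    POSITIVE_CLASS,
    CLASSES,
    SegmentConfig,
    VideoRecord,
    select_inference_segments,
)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "PairedTestResult",
    "predict_video",
    "compute_metrics",
    "roc_auc",
    "paired_tests",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for the positive class (upper GI)."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, labels, predicted, positive: str = POSITIVE_CLASS):
        tp = sum(1 for y, p in zip(labels, predicted) if y == positive and p == positive)
        tn = sum(1 for y, p in zip(labels, predicted) if y != positive and p != positive)
        fp = sum(1 for y, p in zip(labels, predicted) if y != positive and p == positive)
        fn = sum(1 for y, p in zip(labels, predicted) if y == positive and p != positive)
        return cls(TP=tp, TN=tn, FP=fp, FN=fn)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float = float("nan")
    #: names of metrics whose denominator was zero (reported as 0)
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }


def predict_video(
    model,
    video: VideoRecord,
    segment_config: SegmentConfig,
    max_segments: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[float, str]:
    """Aggregate up to ``max_segments`` segment predictions into one label.

    Returns ``(score, label)`` where score is the mean positive-class
    probability over the selected segments.
    """
    segments = select_inference_segments(video, segment_config, max_segments, rng)
    x = np.stack([s.data for s in segments]).astype(np.float64)
    probs = nn.softmax(model.forward(x))
    mean_p = probs.mean(axis=0)
    pos = CLASS_TO_INDEX[POSITIVE_CLASS]
    label = POSITIVE_CLASS if mean_p[pos] >= mean_p[1 - pos] else CLASSES[1 - pos]
    return float(mean_p[pos]), label


def compute_metrics(cm: ConfusionMatrix, auc: float = float("nan")) -> MetricsReport:
    """Accuracy/precision/recall/F1 from counts; zero denominators give 0."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (cm.TP + cm.TN) / cm.total
    precision = ratio(cm.TP, cm.TP + cm.FP, "precision")
    recall = ratio(cm.TP, cm.TP + cm.FN, "recall")
    f1 = ratio(2 * recall * precision, recall + precision, "f1")
    if undefined:
        warnings.warn(
            f"metrics with zero denominator reported as 0: {', '.join(undefined)}",
            RuntimeWarning,
            stacklevel=2,
        )
    return MetricsReport(accuracy, precision, recall, f1, auc, tuple(undefined))


def roc_auc(scores, labels, positive: str = POSITIVE_CLASS):
    """Trapezoidal ROC AUC over all thresholds, plus the ROC points.

    Returns ``(auc, fpr, tpr)``. Equals the Mann-Whitney concordance
    probability. Raises on single-class input.
    """
    from sklearn.metrics import roc_curve, auc as sk_auc

    y = np.asarray([1 if l == positive else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    return float(sk_auc(fpr, tpr)), fpr, tpr


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    t_pvalue: float
    w_statistic: float
    w_pvalue: float
    n_pairs: int
    degenerate: bool = False


def wilcoxon_signed_rank(x, y, exact_max_n: int = 25) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ties get mid-ranks; the statistic is the
    sum of ranks of positive differences. The null distribution is exact
    (rank-sum counting over all sign assignments, handles mid-ranks) for
    n <= ``exact_max_n`` and a continuity-corrected normal approximation
    with tie correction beyond. Returns ``(W, p, n_used)``.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # doubled ranks are integers even with mid-rank ties
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: counts.size - r].copy()
        counts /= counts.sum()
        w2 = int(round(2 * w_pos))
        cdf = counts[: w2 + 1].sum()
        sf = counts[w2:].sum()
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the rank variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return w_pos, float(p), n


def paired_tests(metric_with, metric_without) -> PairedTestResult:
    """Paired t-test and Wilcoxon signed-rank on per-run metric pairs.

    Pairs must be matched by run (same subsets, splits and seeds in both
    arms). If every difference is zero the result is the degenerate
    t = 0, p = 1 (flagged) rather than an error, so sweeping comparisons
    never abort.
    """
    a = np.asarray(metric_with, dtype=float)
    b = np.asarray(metric_without, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D samples with >= 2 pairs")
    if np.all(a == b):
        return PairedTestResult(0.0, 1.0, 0.0, 1.0, len(a), degenerate=True)
    t_res = stats.ttest_rel(a, b)
    w, wp, n_used = wilcoxon_signed_rank(a, b)
    return PairedTestResult(
        float(t_res.statistic), float(t_res.pvalue), w, wp, len(a)
    )
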