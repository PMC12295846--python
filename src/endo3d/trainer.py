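"""Experimental protocol: balanced subsets, splits, training, aggregation.

The study design this module reproduces: the corpus is heavily imbalanced
(few upper-GI, many lower-GI videos), so each experimental run uses every
upper video plus an equal-sized random subset of the lower videos. Runs are
repeated (20 by default) with subsets that are a pure function of the
master seed, so every architecture/segment configuration sees identical
subsets. Each run splits its videos 70:15:15 into train/validation/test at
the video level (stratified by class), trains on randomly sampled segments
(two per optimization step) with Adam on softmax cross-entropy over raw
logits, and is finally evaluated with multi-segment video-level prediction.
Run summaries report per-metric means with Student-t 95% confidence
intervals, per-metric extremes, and the histogram of per-run incorrect
prediction counts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import evaluator
from .blocks import ArchitectureConfig, Model
from .nn import Adam, ConfigurationError, cross_entropy_from_logits
from .segmenter import (
    LOWER,
    UPPER,
    SegmentConfig,
    VideoRecord,
    sample_training_segment,
)

__all__ = [
    "ExperimentConfig",
    "RunResult",
    "RunsSummary",
    "TrainingDivergedError",
    "make_balanced_runs",
    "split_videos",
    "train_run",
    "aggregate_runs",
    "run_seeds",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ExperimentConfig:
    """Protocol parameters (defaults mirror the full-scale study design)."""

    n_runs: int = 20
    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    balanced_per_class: int = 60
    batch_size: int = 2
    learning_rate: float = 1e-4
    epochs: int = 50
    max_inference_segments: int = 10
    master_seed: int = 0
    segment_config: SegmentConfig = field(default_factory=lambda: SegmentConfig(10, 15))
    arch: ArchitectureConfig = field(default_factory=ArchitectureConfig)

    def __post_init__(self):
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ConfigurationError(f"split ratios must sum to 1, got {self.split_ratios}")
        for name in ("n_runs", "balanced_per_class", "batch_size", "epochs",
                     "max_inference_segments"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class RunResult:
    """Everything one run produces."""

    run_index: int
    train_loss: list[float]
    train_accuracy: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    metrics: evaluator.MetricsReport
    confusion: evaluator.ConfusionMatrix
    incorrect_count: int
    #: per-video (video_id, true label, positive score, predicted label)
    predictions: list[tuple[str, str, float, str]]


def run_seeds(master_seed: int, n_runs: int) -> list[np.random.SeedSequence]:
    """Counter-based per-run seed streams derived from the master seed.

    Child 0 of the master sequence is reserved for subset sampling; children
    1..n_runs drive splitting, weight init and segment sampling of each run.
    """
    root = np.random.SeedSequence(master_seed)
    return root.spawn(n_runs + 1)[1:]


def make_balanced_runs(
    upper: list[VideoRecord],
    lower: list[VideoRecord],
    cfg: ExperimentConfig,
) -> list[list[VideoRecord]]:
    """Per-run balanced video sets: all upper + sampled lower, reused across
    configurations.

    The subsets depend only on ``master_seed``, ``n_runs``,
    ``balanced_per_class`` and the video ids, never on the architecture or
    segment configuration.
    """
    if len(lower) < cfg.balanced_per_class:
        raise ConfigurationError(
            f"need at least {cfg.balanced_per_class} majority-class videos, got {len(lower)}"
        )
    if len(upper) > cfg.balanced_per_class:
        raise ConfigurationError(
            f"minority class ({len(upper)}) exceeds balanced_per_class "
            f"({cfg.balanced_per_class}); every minority video must be used"
        )
    subset_rng = np.random.default_rng(np.random.SeedSequence(cfg.master_seed).spawn(1)[0])
    lower_sorted = sorted(lower, key=lambda v: v.video_id)
    runs = []
    for _ in range(cfg.n_runs):
        idx = subset_rng.choice(len(lower_sorted), size=cfg.balanced_per_class, replace=False)
        runs.append(list(upper) + [lower_sorted[i] for i in sorted(idx)])
    return runs


def split_videos(
    videos: list[VideoRecord],
    cfg: ExperimentConfig,
    run_seed: int | np.random.SeedSequence,
):
    """Disjoint, exhaustive 70:15:15 video-level split, stratified by class.

    Within each class the train and validation sizes are ``round(r*n)`` and
    the test split takes the remainder; a split of overall size 0 is a
    configuration error.
    """
    if len(videos) < 3:
        raise ConfigurationError("need at least 3 videos to split")
    rng = np.random.default_rng(run_seed)
    train, val, test = [], [], []
    for label in (UPPER, LOWER):
        group = sorted((v for v in videos if v.label == label), key=lambda v: v.video_id)
        if not group:
            continue
        order = rng.permutation(len(group))
        n = len(group)
        n_train = round(cfg.split_ratios[0] * n)
        n_val = round(cfg.split_ratios[1] * n)
        train += [group[i] for i in order[:n_train]]
        val += [group[i] for i in order[n_train:n_train + n_val]]
        test += [group[i] for i in order[n_train + n_val:]]
    if min(len(train), len(val), len(test)) == 0:
        raise ConfigurationError(
            f"empty split for {len(videos)} videos at ratios {cfg.split_ratios}"
        )
    return train, val, test


def _epoch_pass(model, videos, seg_cfg, rng, batch_size, opt=None):
    """One pass over ``videos``, one fresh segment each; trains when ``opt``."""
    order = rng.permutation(len(videos))
    losses, n_correct = [], 0
    for i in range(0, len(order), batch_size):
        batch = [videos[j] for j in order[i:i + batch_size]]
        segs = [sample_training_segment(v, seg_cfg, rng) for v in batch]
        x = np.stack([s.data for s in segs]).astype(np.float64)
        y = np.array([v.label_index for v in batch])
        logits = model.forward(x)
        loss, dlogits, probs = cross_entropy_from_logits(logits, y)
        if not math.isfinite(loss):
            raise TrainingDivergedError(f"non-finite loss {loss} on batch starting at {i}")
        losses.append(loss * len(batch))
        n_correct += int((probs.argmax(axis=1) == y).sum())
        if opt is not None:
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
    return float(np.sum(losses) / len(videos)), n_correct / len(videos)


def train_run(
    model: Model,
    splits,
    cfg: ExperimentConfig,
    run_seed: int | np.random.SeedSequence,
    run_index: int = 0,
) -> RunResult:
    """Optimize one run and evaluate its test split at the video level.

    Each epoch draws one fresh random segment per training video (batched in
    pairs by default); validation scores one random segment per validation
    video; the test videos are predicted by multi-segment aggregation.
    """
    train, val, test = splits
    ss = run_seed if isinstance(run_seed, np.random.SeedSequence) else np.random.SeedSequence(run_seed)
    seg_ss, val_ss, inf_ss = ss.spawn(3)
    seg_rng = np.random.default_rng(seg_ss)
    val_rng = np.random.default_rng(val_ss)
    inf_rng = np.random.default_rng(inf_ss)

    opt = Adam(model.params(), lr=cfg.learning_rate)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    for _ in range(cfg.epochs):
        tl, ta = _epoch_pass(model, train, cfg.segment_config, seg_rng, cfg.batch_size, opt)
        vl, va = _epoch_pass(model, val, cfg.segment_config, val_rng, cfg.batch_size, None)
        history["train_loss"].append(tl)
        history["train_acc"].append(ta)
        history["val_loss"].append(vl)
        history["val_acc"].append(va)

    predictions = []
    for v in test:
        score, label = evaluator.predict_video(
            model, v, cfg.segment_config, cfg.max_inference_segments, inf_rng
        )
        predictions.append((v.video_id, v.label, score, label))
    cm = evaluator.ConfusionMatrix.from_predictions(
        [p[1] for p in predictions], [p[3] for p in predictions]
    )
    try:
        auc, _, _ = evaluator.roc_auc([p[2] for p in predictions], [p[1] for p in predictions])
    except ValueError:
        auc = float("nan")
    metrics = evaluator.compute_metrics(cm, auc=auc)
    return RunResult(
        run_index=run_index,
        train_loss=history["train_loss"],
        train_accuracy=history["train_acc"],
        val_loss=history["val_loss"],
        val_accuracy=history["val_acc"],
        metrics=metrics,
        confusion=cm,
        incorrect_count=cm.FP + cm.FN,
        predictions=predictions,
    )


@dataclass
class RunsSummary:
    """Multi-run aggregate: means, 95% t-intervals, extremes, error histogram."""

    n_runs: int
    mean: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    maximum: dict[str, float]
    minimum: dict[str, float]
    incorrect_histogram: dict[int, int]


def aggregate_runs(results: list[RunResult]) -> RunsSummary:
    """Average metrics over runs with mean ± t_{0.975,n-1} * sd/sqrt(n) CIs."""
    from scipy import stats

    if len(results) < 2:
        raise ValueError("need at least 2 runs to aggregate")
    n = len(results)
    names = ["accuracy", "precision", "recall", "f1", "auc"]
    values = {m: np.array([getattr(r.metrics, m) for r in results]) for m in names}
    tcrit = stats.t.ppf(0.975, df=n - 1)
    mean, ci, hi, lo = {}, {}, {}, {}
    for m, v in values.items():
        mu = float(np.mean(v))
        half = float(tcrit * np.std(v, ddof=1) / math.sqrt(n))
        mean[m] = mu
        ci[m] = (mu - half, mu + half)
        hi[m] = float(np.max(v))
        lo[m] = float(np.min(v))
    hist = Counter(r.incorrect_count for r in results)
    return RunsSummary(
        n_runs=n,
        mean=mean,
        ci95=ci,
        maximum=hi,
        minimum=lo,
        incorrect_histogram=dict(sorted(hist.items())),
    )
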