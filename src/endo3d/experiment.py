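"""Model/Results front end for the full multi-run experiment.

:class:`GIVideoClassifier` is built from a labeled video corpus plus an
:class:`~endo3d.trainer.ExperimentConfig`; ``fit()`` executes the balanced
multi-run protocol (subset sampling, stratified splits, segment-level
training, video-level testing) and returns a :class:`ExperimentResults`
carrying per-run metrics, their aggregate with 95% confidence intervals,
and comparison/plotting helpers.

Typical use::

    upper, lower, _ = synthgi.generate_corpus(synth_cfg)
    clf = GIVideoClassifier(upper, lower, config)
    res = clf.fit()
    print(res.summary())
    other = GIVideoClassifier(upper, lower, ablated_config).fit()
    print(res.compare(other))     # paired t / Wilcoxon on accuracies
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import evaluator, trainer
from .blocks import build_model
from .segmenter import VideoRecord

__all__ = ["GIVideoClassifier", "ExperimentResults"]


class GIVideoClassifier:
    """Balanced multi-run two-class video classification experiment.

    Parameters
    ----------
    upper, lower : the minority ("upper") and majority ("lower") class
        video lists.
    config : protocol parameters; defaults mirror the full-scale design
        (20 runs, 60 videos per class per run, 70:15:15 splits, Adam at
        1e-4, batch 2, 50 epochs, N=10/G=15 segments).
    """

    def __init__(self, upper: list[VideoRecord], lower: list[VideoRecord],
                 config: trainer.ExperimentConfig | None = None, **overrides):
        self.config = config or trainer.ExperimentConfig()
        if overrides:
            self.config = replace(self.config, **overrides)
        self.upper = list(upper)
        self.lower = list(lower)

    @classmethod
    def from_corpus(cls, videos: list[VideoRecord],
                    config: trainer.ExperimentConfig | None = None, **overrides):
        """Split a mixed video list by label and construct the experiment."""
        upper = [v for v in videos if v.label == "upper"]
        lower = [v for v in videos if v.label == "lower"]
        return cls(upper, lower, config, **overrides)

    def fit(self, progress: bool = False) -> "ExperimentResults":
        """Run the full protocol; deterministic per ``config.master_seed``."""
        cfg = self.config
        subsets = trainer.make_balanced_runs(self.upper, self.lower, cfg)
        seeds = trainer.run_seeds(cfg.master_seed, cfg.n_runs)
        results, models = [], []
        for i, (videos, seed) in enumerate(zip(subsets, seeds)):
            split_ss, init_ss, train_ss = seed.spawn(3)
            splits = trainer.split_videos(videos, cfg, split_ss)
            model = build_model(cfg.arch, seed=init_ss)
            res = trainer.train_run(model, splits, cfg, train_ss, run_index=i)
            results.append(res)
            models.append(model)
            if progress:
                print(
                    f"run {i}: test accuracy {res.metrics.accuracy:.3f} "
                    f"({res.incorrect_count} incorrect)"
                )
        return ExperimentResults(self, results, models)


@dataclass
class ExperimentResults:
    """Estimates and diagnostics from a fitted experiment."""

    model: GIVideoClassifier
    runs: list[trainer.RunResult]
    fitted_models: list

    @property
    def aggregate(self) -> trainer.RunsSummary:
        return trainer.aggregate_runs(self.runs)

    @property
    def metrics_frame(self) -> pd.DataFrame:
        """Per-run metric table (one row per run)."""
        rows = []
        for r in self.runs:
            row = {"run": r.run_index, **r.metrics.as_dict(),
                   "incorrect": r.incorrect_count}
            rows.append(row)
        return pd.DataFrame(rows).set_index("run")

    def conf_int(self) -> pd.DataFrame:
        agg = self.aggregate
        return pd.DataFrame(
            {m: {"lower": lo, "upper": hi} for m, (lo, hi) in agg.ci95.items()}
        ).T

    def summary(self) -> str:
        """Human-readable aggregate in the style of a fit report."""
        agg = self.aggregate
        cfg = self.model.config
        lines = [
            "Balanced multi-run video classification",
            "=" * 55,
            f"runs: {agg.n_runs}   videos/run: "
            f"{len(self.model.upper) + cfg.balanced_per_class}   "
            f"segments: N={cfg.segment_config.frames_per_segment} "
            f"G={cfg.segment_config.frame_gap} (span {cfg.segment_config.span})",
            f"epochs: {cfg.epochs}   batch: {cfg.batch_size}   "
            f"lr: {cfg.learning_rate:g}   attention: {cfg.arch.use_attention}",
            "-" * 55,
            f"{'metric':<10}{'mean':>8}{'95% CI':>20}{'min':>8}{'max':>8}",
        ]
        for m in ("accuracy", "precision", "recall", "f1", "auc"):
            lo, hi = agg.ci95[m]
            lines.append(
                f"{m:<10}{agg.mean[m]:>8.3f}{f'({lo:.3f}, {hi:.3f})':>20}"
                f"{agg.minimum[m]:>8.3f}{agg.maximum[m]:>8.3f}"
            )
        lines.append("-" * 55)
        hist = ", ".join(f"{k}: {v}" for k, v in agg.incorrect_histogram.items())
        lines.append(f"incorrect predictions per run (count: runs): {hist}")
        return "\n".join(lines)

    def compare(self, other: "ExperimentResults",
                metric: str = "accuracy") -> evaluator.PairedTestResult:
        """Paired t and Wilcoxon signed-rank tests against another arm.

        Both experiments must have used the same master seed so runs are
        matched pairs.
        """
        a = [getattr(r.metrics, metric) for r in self.runs]
        b = [getattr(r.metrics, metric) for r in other.runs]
        return evaluator.paired_tests(a, b)

    def plot_roc(self, run: int = 0, ax=None):
        """ROC curve of one run's video-level scores."""
        import matplotlib.pyplot as plt

        r = self.runs[run]
        auc, fpr, tpr = evaluator.roc_auc(
            [p[2] for p in r.predictions], [p[1] for p in r.predictions]
        )
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"run {run} (AUC = {auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax

    def save_json(self, path: str):
        """Per-run metrics and the aggregate, as JSON."""
        agg = self.aggregate
        payload = {
            "runs": [
                {"run": r.run_index, **r.metrics.as_dict(), "incorrect": r.incorrect_count}
                for r in self.runs
            ],
            "mean": agg.mean,
            "ci95": {k: list(v) for k, v in agg.ci95.items()},
            "incorrect_histogram": {str(k): v for k, v in agg.incorrect_histogram.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
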