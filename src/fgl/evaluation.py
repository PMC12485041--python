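"""Metrics and result tables: per-horizon MSE, percent reduction, AUC-ROC,
sensitivity/FPR, and the tidy horizon-by-variant result assembly.

Benchmark MSEs for binned forecasting are reported in bin-index units
(squared distance between the predicted and true bin index): that is the
scale on which distilled and baseline students are compared, and it makes
errors directly comparable across bin resolutions of the same signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "mse",
    "percent_reduction",
    "auc_roc",
    "sensitivity_fpr",
    "horizon_table",
    "HorizonResults",
    "ClassificationReport",
]


def mse(predictions, targets) -> float:
    """Mean squared error between two equal-length sequences."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("mse of empty sequences is undefined")
    return float(np.mean((p - t) ** 2))


def percent_reduction(baseline_mse: float, fgl_mse: float) -> float:
    """Percent reduction of ``fgl_mse`` relative to ``baseline_mse``."""
    if baseline_mse <= 0:
        raise ValueError("baseline MSE must be positive")
    return 100.0 * (baseline_mse - fgl_mse) / baseline_mse


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return labels


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney formulation; ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    return float(roc_auc_score(labels, scores))


def sensitivity_fpr(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, FPR) of the rule ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    return tp / (tp + fn), fp / (fp + tn)


@dataclass
class ClassificationReport:
    """Per-seed event-forecasting replicates with mean and variance."""

    rows: pd.DataFrame  # columns: seed, variant, auc, sensitivity, fpr

    def aggregate(self) -> pd.DataFrame:
        g = self.rows.groupby("variant")[["auc", "sensitivity", "fpr"]]
        out = g.agg(["mean", "var"])
        return out

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


@dataclass
class HorizonResults:
    """Tidy per-(horizon, variant, seed) MSE table with explicit exclusions.

    ``exclusions`` is a list of ``(horizon, variant)`` cells annotated as
    outliers; excluded cells are *kept in the table* and only dropped from
    the aggregate, with the exclusion recorded — never silently deleted.
    """

    table: pd.DataFrame  # columns: horizon, variant, seed, mse
    exclusions: list = field(default_factory=list)

    def per_horizon(self) -> pd.DataFrame:
        """Seed-averaged MSE per (horizon, variant)."""
        return (
            self.table.groupby(["horizon", "variant"])["mse"].mean().reset_index()
        )

    def aggregate(self, apply_exclusions: bool = True) -> dict[str, float]:
        """Mean over horizons (of seed means) per variant."""
        ph = self.per_horizon()
        if apply_exclusions:
            for h, v in self.exclusions:
                ph = ph[~((ph["horizon"] == h) & (ph["variant"] == v))]
        return {v: float(g["mse"].mean()) for v, g in ph.groupby("variant")}

    def replicate_stats(self) -> pd.DataFrame:
        return (
            self.table.groupby(["horizon", "variant"])["mse"]
            .agg(["mean", "var"])
            .reset_index()
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self, baseline: str = "baseline") -> dict:
        """Aggregates plus percent reductions of every variant vs the baseline."""
        agg = self.aggregate()
        reductions = {
            v: percent_reduction(agg[baseline], m)
            for v, m in agg.items()
            if v != baseline and baseline in agg
        }
        return {
            "aggregate_mse": agg,
            "percent_reduction_vs_baseline": reductions,
            "exclusions": [list(e) for e in self.exclusions],
        }

    def save_summary(self, path, baseline: str = "baseline") -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(baseline), fh, indent=2)


def horizon_table(runs, exclusions: list | None = None) -> HorizonResults:
    """Assemble per-run records into a :class:`HorizonResults`.

    ``runs`` is an iterable of mappings with keys ``horizon``, ``variant``,
    ``seed`` and ``mse``.  Every (horizon, variant) pair present anywhere
    must have at least one run; a missing combination is reported as a gap.
    """
    table = pd.DataFrame(list(runs))
    required = {"horizon", "variant", "seed", "mse"}
    if table.empty or not required.issubset(table.columns):
        raise ValueError(f"runs must provide columns {sorted(required)}")
    if (table["mse"] < 0).any():
        raise ValueError("MSE must be non-negative")
    horizons = sorted(table["horizon"].unique())
    variants = sorted(table["variant"].unique())
    gaps = [
        (h, v)
        for h in horizons
        for v in variants
        if table[(table["horizon"] == h) & (table["variant"] == v)].empty
    ]
    if gaps:
        raise ValueError(f"missing (horizon, variant) cells: {gaps}")
    return HorizonResults(table=table, exclusions=list(exclusions or []))
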