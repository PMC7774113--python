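"""Aggregation of per-image ECS values into reporting quantities.

Per-image scores live in a "score table" — a pandas DataFrame with one
row per (image, model, method, S, K) — from which this module computes
grouped means, percentile-bootstrap 95% confidence intervals, severity
strata and full S/K sensitivity sweeps with per-setting method
rankings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ecs import EmptyExpertError, ecs_score
from .grids import GridSpec, Heatmap, LesionMaskSet, discretize_expert, discretize_heatmap
from .weights import WeightSet

__all__ = [
    "SCORE_COLUMNS",
    "EvalRecord",
    "validate_score_table",
    "mean_ecs",
    "bootstrap_ci",
    "stratify_by_grade",
    "sensitivity_sweep",
    "rank_methods",
    "plot_mean_scores",
]

logger = logging.getLogger("lesionecs")

#: Required columns of a score table.
SCORE_COLUMNS = ("image_id", "model", "method", "S", "K", "score")


@dataclass
class EvalRecord:
    """One (image, heatmap) pair queued for scoring."""

    image_id: str
    masks: LesionMaskSet
    heatmap: Heatmap | np.ndarray
    model: str = ""
    method: str = ""
    grade: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.grade is None and self.masks.grade is not None:
            self.grade = self.masks.grade


def validate_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check score-table invariants: required columns, scores in [0, 1], unique keys."""
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table is missing columns {missing}")
    s = table["score"]
    if ((s < 0) | (s > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    keys = ["image_id", "model", "method", "S", "K"]
    if table.duplicated(subset=keys).any():
        raise ValueError(f"duplicate rows for key {keys}")
    return table


def mean_ecs(
    table: pd.DataFrame, group_keys: Sequence[str] | None = ("model", "method")
) -> pd.Series | float:
    """Arithmetic mean score, optionally grouped.

    With ``group_keys=None`` returns the overall mean as a float.
    """
    if len(table) == 0:
        raise ValueError("cannot average an empty score table")
    if not group_keys:
        return float(table["score"].mean())
    return table.groupby(list(group_keys), sort=True)["score"].mean()


def bootstrap_ci(
    scores: Sequence[float],
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for the mean score.

    Resamples images with replacement ``n_boot`` times and returns the
    (1-level)/2 and 1-(1-level)/2 percentiles of the resampled means.
    """
    x = np.asarray(list(scores), dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 scores for a confidence interval, got {x.size}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(low), float(high)


def stratify_by_grade(
    table: pd.DataFrame,
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-severity-grade mean, CI and image count.

    Strata with a single image report the mean only (CI columns NaN) —
    an interval from one observation would be meaningless.
    """
    if "grade" not in table.columns:
        raise ValueError("score table has no 'grade' column")
    rows = []
    for grade, group in table.dropna(subset=["grade"]).groupby("grade", sort=True):
        scores = group["score"].to_numpy()
        row = {
            "grade": int(grade),
            "n": len(scores),
            "mean": float(scores.mean()),
            "ci_low": np.nan,
            "ci_high": np.nan,
        }
        if len(scores) >= 2:
            row["ci_low"], row["ci_high"] = bootstrap_ci(
                scores, level=level, n_boot=n_boot, seed=seed
            )
        rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_sweep(
    records: Iterable[EvalRecord],
    s_values: Sequence[int],
    k_values: Sequence[int],
    weights: WeightSet,
    channel_mode: str = "abs-max",
) -> pd.DataFrame:
    """Recompute ECS for every record under every (S, K) combination.

    Images whose expert map is empty at a given grid are skipped with a
    log record, mirroring their exclusion from dataset averages.
    Returns a score table with one row per (record, S, K).
    """
    records = list(records)
    if not records:
        raise ValueError("no records to evaluate")
    for v in list(s_values) + list(k_values):
        if v < 1:
            raise ValueError(f"grid sizes and K values must be >= 1, got {v}")
    rows = []
    for s in s_values:
        grids: dict[tuple[int, int], GridSpec] = {}
        for rec in records:
            shape = rec.masks.shape
            if shape not in grids:
                grids[shape] = GridSpec(shape, s)
            grid = grids[shape]
            heat = rec.heatmap if isinstance(rec.heatmap, Heatmap) else Heatmap(rec.heatmap)
            de = discretize_expert(rec.masks, weights, grid)
            dh = discretize_heatmap(heat, grid)
            for k in k_values:
                try:
                    res = ecs_score(de, dh, k)
                except EmptyExpertError:
                    logger.info(
                        "skipping image %s at S=%d, K=%d: empty expert annotation",
                        rec.image_id, s, k,
                    )
                    continue
                rows.append(
                    {
                        "image_id": rec.image_id,
                        "model": rec.model,
                        "method": rec.method,
                        "S": s,
                        "K": k,
                        "score": res.score,
                        "overlap": res.overlap,
                        "denominator": res.denominator,
                        "grade": rec.grade,
                    }
                )
    if not rows:
        raise ValueError("all images were skipped; no scores computed")
    return validate_score_table(pd.DataFrame(rows))


def rank_methods(table: pd.DataFrame) -> dict[tuple[int, int], tuple[str, ...]]:
    """Method ranking (best mean first) for each (S, K) setting.

    Ties are resolved alphabetically so rankings are deterministic.
    """
    out: dict[tuple[int, int], tuple[str, ...]] = {}
    for (s, k), group in table.groupby(["S", "K"], sort=True):
        means = group.groupby("method", sort=True)["score"].mean()
        ranked = means.sort_values(ascending=False, kind="stable")
        out[(int(s), int(k))] = tuple(ranked.index)
    return out


def plot_mean_scores(table: pd.DataFrame, path=None):
    """Bar chart of mean ECS per (model, method) with bootstrap CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = mean_ecs(table, ("model", "method"))
    labels = [f"{m}\n{h}" for m, h in means.index]
    errs = np.array(
        [
            np.abs(
                np.array(bootstrap_ci(g["score"], n_boot=2000)) - g["score"].mean()
            )
            for _, g in table.groupby(["model", "method"], sort=True)
        ]
    ).T
    fig, ax = plt.subplots(figsize=(max(6, len(labels)), 4))
    ax.bar(range(len(means)), means.to_numpy(), yerr=errs, capsize=3)
    ax.set_xticks(range(len(labels)), labels, fontsize=8)
    ax.set_ylabel("mean ECS")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
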