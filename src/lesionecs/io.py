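"""Readers/writers for masks, heatmaps, manifests and evaluation runs.

Masks travel as binary PNG/TIFF images (any nonzero pixel is lesion),
heatmaps as dense NPY arrays or single/three-channel images, and a
dataset is described by a manifest CSV with one row per
(image, model, method) triple.  ``run_evaluate`` drives the whole
pipeline over a manifest and writes deterministic CSV/JSON reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import stats as _stats
from .ecs import EmptyExpertError, ecs_per_lesion, ecs_score, random_baseline
from .grids import (
    LESION_TYPES,
    GridSpec,
    Heatmap,
    LesionMaskSet,
    discretize_expert,
    discretize_heatmap,
    reduce_channels,
)
from .weights import WeightSet, get_preset

logger = logging.getLogger("lesionecs")

__all__ = [
    "EvalConfig",
    "read_mask",
    "write_mask",
    "read_heatmap",
    "write_heatmap",
    "load_manifest",
    "run_evaluate",
]

MANIFEST_MASK_COLUMNS = tuple(f"{t}_path" for t in LESION_TYPES)


@dataclass
class EvalConfig:
    """Settings for an evaluation run.

    ``k_values`` defaults to the standard sensitivity sweep {10,15,20};
    ``k`` is the headline setting reported in aggregates.
    """

    grid_size: int = 10
    k: int = 15
    k_values: tuple[int, ...] = (10, 15, 20)
    weights: str | WeightSet = "idrid-paper"
    channel_mode: str = "abs-max"
    n_boot: int = 10_000
    seed: int = 0
    per_lesion: bool = True

    def resolve_weights(self) -> WeightSet:
        return self.weights if isinstance(self.weights, WeightSet) else get_preset(self.weights)

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalConfig":
        raw = json.loads(Path(path).read_text())
        if "weights" in raw and isinstance(raw["weights"], dict):
            raw["weights"] = WeightSet(**raw["weights"])
        if "k_values" in raw:
            raw["k_values"] = tuple(raw["k_values"])
        return cls(**raw)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a binary lesion mask; any nonzero pixel becomes 1."""
    path = Path(path)
    try:
        img = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read mask file {path}: {exc}") from exc
    if img.size == 0:
        raise OSError(f"mask file {path} is empty")
    if img.ndim == 3:  # RGB(A): any channel nonzero counts
        img = img[..., :3].max(axis=2)
    return (img != 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask) != 0).astype(np.uint8) * 255)


def read_heatmap(path: str | Path) -> np.ndarray:
    """Load a raw heatmap (NPY, or single/three-channel image) as float."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
    else:
        try:
            arr = iio.imread(path)
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot read heatmap file {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3 and arr.shape[2] > 3:
        raise ValueError(
            f"heatmap {path} has {arr.shape[2]} channels; at most 3 supported"
        )
    if arr.ndim not in (2, 3):
        raise ValueError(f"heatmap {path} has unsupported ndim={arr.ndim}")
    return arr


def write_heatmap(path: str | Path, values: np.ndarray) -> None:
    np.save(Path(path), np.asarray(values, dtype=float))


def as_single_channel(raw: np.ndarray, mode: str = "abs-max") -> Heatmap:
    """Reduce to one channel if needed; 2-D inputs pass through (clipped at 0)."""
    if raw.ndim == 3:
        return reduce_channels(raw, mode=mode)
    return Heatmap(np.clip(raw, 0.0, None))


def load_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a dataset manifest CSV.

    Required columns: ``image_id``, the four per-lesion mask paths,
    ``model``, ``method``, ``heatmap_path``; optional ``grade`` and
    ``split`` (tuning|test).  Relative paths resolve against the
    manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"manifest {path} is empty")
    required = ["image_id", *MANIFEST_MASK_COLUMNS, "model", "method", "heatmap_path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns {missing}")
    if df.duplicated(subset=["image_id", "model", "method"]).any():
        raise ValueError("manifest has duplicate (image_id, model, method) rows")
    base = path.parent
    for col in (*MANIFEST_MASK_COLUMNS, "heatmap_path"):
        df[col] = df[col].map(lambda p: str((base / p).resolve()) if not Path(p).is_absolute() else p)
        if check_files:
            for p in df[col]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")
    return df


def _load_mask_set(row: pd.Series) -> LesionMaskSet:
    masks = {t: read_mask(row[f"{t}_path"]) for t in LESION_TYPES}
    grade = None
    if "grade" in row.index and pd.notna(row.get("grade")):
        grade = int(row["grade"])
    return LesionMaskSet(grade=grade, **masks)


def run_evaluate(
    manifest: pd.DataFrame, config: EvalConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, dict]:
    """Score every manifest row and aggregate.

    Computes per-image ECS for each (model, method) pair at every K in
    ``config.k_values`` on the configured grid, plus per-lesion scores
    (unweighted) at the headline K.  Images with empty expert
    annotation are skipped with a warning; missing heatmap files are
    reported, not fatal.  Returns the score table and an aggregate
    report; both are written under ``out_dir`` when given (byte-stable
    for fixed inputs and seed — timestamps appear only in logs).
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    weights = config.resolve_weights()
    rows: list[dict] = []
    lesion_rows: list[dict] = []

    for _, row in manifest.iterrows():
        try:
            masks = _load_mask_set(row)
            raw = read_heatmap(row["heatmap_path"])
        except (OSError, FileNotFoundError) as exc:
            logger.warning("skipping %s/%s/%s: %s", row["image_id"], row["model"], row["method"], exc)
            continue
        grid = GridSpec(masks.shape, config.grid_size)
        heat = as_single_channel(raw, config.channel_mode)
        de = discretize_expert(masks, weights, grid)
        dh = discretize_heatmap(heat, grid)
        common = {
            "image_id": row["image_id"],
            "model": row["model"],
            "method": row["method"],
            "grade": masks.grade,
            "split": row.get("split", ""),
        }
        for k in config.k_values:
            try:
                res = ecs_score(de, dh, k)
            except EmptyExpertError:
                logger.warning("image %s has empty expert annotation; skipped", row["image_id"])
                break
            rows.append(
                {**common, "S": config.grid_size, "K": k, "score": res.score,
                 "overlap": res.overlap, "denominator": res.denominator}
            )
        if config.per_lesion:
            for lesion in LESION_TYPES:
                try:
                    res = ecs_per_lesion(masks, dh, config.k, lesion, grid)
                except EmptyExpertError:
                    logger.info("image %s: no %s annotation; per-lesion score skipped",
                                row["image_id"], lesion)
                    continue
                lesion_rows.append(
                    {**common, "S": config.grid_size, "K": config.k,
                     "lesion": lesion, "score": res.score}
                )

    if not rows:
        raise ValueError("no image could be scored from this manifest")
    table = pd.DataFrame(rows).sort_values(["model", "method", "K", "image_id"], kind="stable")
    table = table.reset_index(drop=True)
    _stats.validate_score_table(table)
    lesion_table = pd.DataFrame(lesion_rows)

    aggregates = _aggregate(table, lesion_table, config)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "scores.csv", index=False)
        if len(lesion_table):
            lesion_table.to_csv(out / "scores_per_lesion.csv", index=False)
        (out / "aggregates.json").write_text(json.dumps(aggregates, indent=2) + "\n")
    return table, aggregates


def _aggregate(table: pd.DataFrame, lesion_table: pd.DataFrame, config: EvalConfig) -> dict:
    head = table[table["K"] == config.k]
    report: dict = {"S": config.grid_size, "K": config.k, "groups": []}
    for (model, method), group in head.groupby(["model", "method"], sort=True):
        scores = group["score"].to_numpy()
        entry = {
            "model": model, "method": method, "n": int(len(scores)),
            "mean": float(scores.mean()), "ci": None,
        }
        if len(scores) >= 2:
            entry["ci"] = list(
                _stats.bootstrap_ci(scores, n_boot=config.n_boot, seed=config.seed)
            )
        report["groups"].append(entry)
    if "grade" in head.columns and head["grade"].notna().any():
        strata = _stats.stratify_by_grade(head, n_boot=config.n_boot, seed=config.seed)
        report["by_grade"] = json.loads(strata.to_json(orient="records"))
    if len(lesion_table):
        report["by_lesion"] = [
            {"model": m, "method": h, "lesion": l, "n": int(len(g)),
             "mean": float(g["score"].mean())}
            for (m, h, l), g in lesion_table.groupby(["model", "method", "lesion"], sort=True)
        ]
    report["by_k"] = [
        {"K": int(k), "mean": float(g["score"].mean())}
        for k, g in table.groupby("K", sort=True)
    ]
    return report


def baseline_for_manifest(
    manifest: pd.DataFrame, config: EvalConfig, n_draws: int = 10_000
) -> dict:
    """Random-importance baseline averaged over the manifest's images."""
    weights = config.resolve_weights()
    rng = np.random.default_rng(config.seed)
    means, ses = [], []
    seen: set[str] = set()
    for _, row in manifest.iterrows():
        if row["image_id"] in seen:
            continue
        seen.add(row["image_id"])
        masks = _load_mask_set(row)
        grid = GridSpec(masks.shape, config.grid_size)
        de = discretize_expert(masks, weights, grid)
        if de.nnz() == 0:
            logger.warning("image %s has empty expert annotation; skipped", row["image_id"])
            continue
        res = random_baseline(de, config.k, n_draws=n_draws, seed=rng)
        means.append(res.mean)
        ses.append(res.se)
    if not means:
        raise ValueError("no image with annotations in manifest")
    return {
        "mean": float(np.mean(means)),
        "per_image_se": float(np.mean(ses)),
        "n_images": len(means),
        "n_draws": n_draws,
    }
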