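"""The Explainability Consistency Score (ECS).

ECS measures, on an S x S grid, how well the most important cells of a
model attribution heatmap agree with the most lesion-dense cells of an
expert segmentation:

    ECS(DE, DH) = |top_k(DE) ∩ top_k(DH)| / min(K, nnz(DE))

where ``DE`` is the (lesion-weighted) discretized expert segmentation,
``DH`` the discretized heatmap, ``top_k`` returns the K cells with the
highest value, and ``nnz`` counts nonzero expert cells.  Dividing by
``min(K, nnz(DE))`` keeps the score in [0, 1] even when fewer than K
cells contain any annotated lesion, so it reads as the fraction of the
relevant expert cells the heatmap recovered.

Conventions adopted here (the published formula is silent on both):

* only strictly positive cells are eligible for a top-K set, so a
  sparse map contributes fewer than K cells rather than arbitrary
  zero-mass cells;
* ties are broken deterministically — higher value first, then
  row-major cell index — so scores are reproducible.  A seeded
  randomized tie-break is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import (
    DiscretizedMap,
    GridSpec,
    LesionMaskSet,
    discretize_heatmap,
)

__all__ = [
    "EmptyExpertError",
    "EcsResult",
    "BaselineResult",
    "top_k_cells",
    "ranked_cells",
    "ecs_score",
    "ecs_per_lesion",
    "random_baseline",
]


class EmptyExpertError(ValueError):
    """The expert map has no positive cell, so the score is undefined."""


@dataclass(frozen=True)
class EcsResult:
    """Per-image ECS with the ingredients that produced it.

    ``score == overlap / denominator`` with
    ``denominator = min(k, nnz(DE))``.
    """

    score: float
    k: int
    expert_top_cells: frozenset[tuple[int, int]]
    heatmap_top_cells: frozenset[tuple[int, int]]
    denominator: int
    overlap: int


@dataclass(frozen=True)
class BaselineResult:
    """Mean and standard error of the random-importance baseline."""

    mean: float
    se: float
    n_draws: int


def _cells_of(d: DiscretizedMap | np.ndarray) -> np.ndarray:
    return d.cells if isinstance(d, DiscretizedMap) else np.asarray(d, dtype=float)


def ranked_cells(
    d: DiscretizedMap | np.ndarray,
    tie_break: str = "row-major",
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """All strictly positive cells, most valuable first.

    Ordered by value descending; equal values by row-major index
    ascending (``tie_break="row-major"``) or in seeded random order
    (``tie_break="random"``, requires ``rng``).
    """
    cells = _cells_of(d)
    flat = cells.ravel()
    if tie_break == "row-major":
        secondary = np.arange(flat.size)
    elif tie_break == "random":
        if rng is None:
            raise ValueError("tie_break='random' requires an rng")
        secondary = rng.permutation(flat.size)
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    # lexsort: last key is primary. Sort by (-value, secondary index).
    order = np.lexsort((secondary, -flat))
    order = order[flat[order] > 0]
    s = cells.shape[1]
    return [(int(ix) // s, int(ix) % s) for ix in order]


def top_k_cells(
    d: DiscretizedMap | np.ndarray,
    k: int,
    tie_break: str = "row-major",
    rng: np.random.Generator | None = None,
) -> set[tuple[int, int]]:
    """The (row, col) indices of the K highest-valued positive cells.

    Returns fewer than ``k`` cells when fewer than ``k`` cells are
    strictly positive; zero-valued cells never enter the set.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return set(ranked_cells(d, tie_break=tie_break, rng=rng)[:k])


def ecs_score(
    de: DiscretizedMap | np.ndarray,
    dh: DiscretizedMap | np.ndarray,
    k: int,
    tie_break: str = "row-major",
    rng: np.random.Generator | None = None,
) -> EcsResult:
    """ECS between a discretized expert map and a discretized heatmap.

    Raises
    ------
    EmptyExpertError
        If the expert map has no positive cell (image carries no
        annotated lesion; such images are excluded from averages).
    """
    de_cells = _cells_of(de)
    dh_cells = _cells_of(dh)
    if de_cells.shape != dh_cells.shape:
        raise ValueError(
            f"expert and heatmap grids differ: {de_cells.shape} vs {dh_cells.shape}"
        )
    nnz = int(np.count_nonzero(de_cells > 0))
    if nnz == 0:
        raise EmptyExpertError(
            "expert map has no positive cell; ECS is undefined for images "
            "without annotated lesions"
        )
    expert_top = top_k_cells(de_cells, k, tie_break=tie_break, rng=rng)
    heat_top = top_k_cells(dh_cells, k, tie_break=tie_break, rng=rng)
    overlap = len(expert_top & heat_top)
    denominator = min(k, nnz)
    return EcsResult(
        score=overlap / denominator,
        k=k,
        expert_top_cells=frozenset(expert_top),
        heatmap_top_cells=frozenset(heat_top),
        denominator=denominator,
        overlap=overlap,
    )


def ecs_per_lesion(
    masks: LesionMaskSet,
    dh: DiscretizedMap | np.ndarray,
    k: int,
    lesion: str,
    grid: GridSpec,
) -> EcsResult:
    """ECS against a single lesion type, without weighting.

    The selected mask is discretized on its own (weight 1) and compared
    to ``dh``.  An empty mask raises :class:`EmptyExpertError`, which
    callers treat as a skip signal for that (image, lesion) pair.
    """
    mask = masks.mask(lesion)
    de = discretize_heatmap(mask.astype(float), grid)
    if de.nnz() == 0:
        raise EmptyExpertError(
            f"lesion {lesion!r} has no annotated pixel in this image; skipped"
        )
    return ecs_score(DiscretizedMap(de.cells, kind="expert", grid=grid), dh, k)


def random_baseline(
    de: DiscretizedMap | np.ndarray,
    k: int,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> BaselineResult:
    """Expected ECS of a heatmap that attributes importance at random.

    Each draw assigns i.i.d. uniform(0, 1) values to the grid cells
    (equivalently, a uniformly random cell ranking) and scores it
    against ``de``; randomization is at cell level because pixel-level
    noise would average out to near-uniform cell sums and so would not
    emulate random importance rankings.  Returns the Monte-Carlo mean
    and standard error; fully reproducible for a given seed.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    de_cells = _cells_of(de)
    s = de_cells.shape[0]
    scores = np.empty(n_draws)
    for i in range(n_draws):
        random_cells = rng.uniform(size=(s, s))
        scores[i] = ecs_score(de_cells, random_cells, k).score
    se = float(scores.std(ddof=1) / np.sqrt(n_draws)) if n_draws > 1 else float("nan")
    return BaselineResult(mean=float(scores.mean()), se=se, n_draws=n_draws)
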