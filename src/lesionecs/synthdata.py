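"""Synthetic IDRiD-style fixtures: lesion masks, heatmaps, toy scorers.

The generator emulates the *structure* of pixel-level diabetic
retinopathy annotation sets — four binary masks per image (hemorrhages,
microaneurysms, soft exudates, hard exudates) with highly imbalanced
pixel counts (target profile ~47% HE / 44% EX / 8% SE / 1% MA of all
lesion pixels over a corpus) — without attempting fundus-photograph
appearance.  Lesions are filled ellipses (HE/EX/SE) and 1-4 pixel dots
(MA): the agreement score depends only on pixel membership, so
morphological realism is unnecessary.

It also builds heatmaps with an exactly controlled top-K cell overlap
against an expert discretization (for parameter-recovery testing) and
closed-form score functions for the attribution methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .ecs import ranked_cells
from .grids import GridSpec, Heatmap, LesionMaskSet, discretize_expert
from .saliency import ScoreFunction
from .weights import WeightSet

__all__ = [
    "FixtureParams",
    "InfeasibleGeometryError",
    "InfeasibleOverlapError",
    "generate_mask_set",
    "generate_corpus",
    "generate_heatmap_with_overlap",
    "toy_scorer",
]


class InfeasibleGeometryError(ValueError):
    """Requested lesions cannot fit in the image geometry."""


class InfeasibleOverlapError(ValueError):
    """The requested top-K overlap cannot be constructed."""


# MA dots: pixel offsets for sizes 1-4
_DOT_OFFSETS = {
    1: [(0, 0)],
    2: [(0, 0), (0, 1)],
    3: [(0, 0), (0, 1), (1, 0)],
    4: [(0, 0), (0, 1), (1, 0), (1, 1)],
}


@dataclass(frozen=True)
class FixtureParams:
    """Generator settings for one synthetic annotation corpus.

    Per-lesion-type ``*_count`` ranges are inclusive (min, max) lesion
    counts per image; ``*_radius`` are inclusive ellipse semi-axis
    ranges in pixels, and ``ma_size`` the dot size in pixels (1-4).
    The defaults target the 47/44/8/1 HE/EX/SE/MA corpus pixel-fraction
    profile: with mean counts and sizes below, expected pixel mass is
    roughly 616 HE : 565 EX : 100 SE : 12.5 MA per image (~49:45:8:1).

    ``grade_probs`` drives the severity label (grades 0-4); the default
    mirrors the grade composition of the 54-image tuning split this
    corpus emulates (one grade-1 image, 18/16/19 of grades 2-4).

    ``cluster_radius``, if set, confines all lesion centers to a disk
    of that radius (random center unless ``cluster_center`` is given),
    emulating the regional concentration of DR lesions; ``None`` places
    lesions uniformly over the image.
    """

    image_size: int = 128
    he_count: tuple[int, int] = (3, 5)
    he_radius: tuple[int, int] = (5, 9)
    ex_count: tuple[int, int] = (4, 6)
    ex_radius: tuple[int, int] = (4, 8)
    se_count: tuple[int, int] = (1, 3)
    se_radius: tuple[int, int] = (3, 5)
    ma_count: tuple[int, int] = (3, 7)
    ma_size: tuple[int, int] = (1, 4)
    grade_probs: tuple[float, ...] = (0.0, 1 / 54, 18 / 54, 16 / 54, 19 / 54)
    cluster_center: tuple[int, int] | None = None
    cluster_radius: int | None = None

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if abs(sum(self.grade_probs) - 1.0) > 1e-9:
            raise ValueError("grade_probs must sum to 1")
        max_r = max(self.he_radius[1], self.ex_radius[1], self.se_radius[1])
        if 2 * max_r >= self.image_size:
            raise InfeasibleGeometryError(
                f"lesion radius {max_r} does not fit in a {self.image_size}px image"
            )
        if self.cluster_radius is not None and self.cluster_radius + max_r >= self.image_size // 2:
            raise InfeasibleGeometryError(
                "cluster disk plus lesion radius exceeds the image half-size"
            )


def _lesion_center(
    rng: np.random.Generator, n: int, margin: int, params: FixtureParams
) -> tuple[int, int]:
    if params.cluster_radius is None:
        lo, hi = margin, n - margin
        if lo >= hi:
            raise InfeasibleGeometryError("lesion too large for the image")
        return int(rng.integers(lo, hi)), int(rng.integers(lo, hi))
    cr, cc = params.cluster_center or (n // 2, n // 2)
    # rejection-sample a point in the cluster disk
    for _ in range(1000):
        r = int(rng.integers(cr - params.cluster_radius, cr + params.cluster_radius + 1))
        c = int(rng.integers(cc - params.cluster_radius, cc + params.cluster_radius + 1))
        if (r - cr) ** 2 + (c - cc) ** 2 <= params.cluster_radius**2 and margin <= r < n - margin and margin <= c < n - margin:
            return r, c
    raise InfeasibleGeometryError("could not place a lesion inside the cluster disk")


def generate_mask_set(
    params: FixtureParams, seed: int | np.random.Generator
) -> LesionMaskSet:
    """Draw one synthetic four-mask annotation set; reproducible per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.image_size
    masks: dict[str, np.ndarray] = {}

    for lesion, (count_range, radius_range) in {
        "he": (params.he_count, params.he_radius),
        "ex": (params.ex_count, params.ex_radius),
        "se": (params.se_count, params.se_radius),
    }.items():
        m = np.zeros((n, n), dtype=np.uint8)
        count = int(rng.integers(count_range[0], count_range[1] + 1))
        for _ in range(count):
            a = int(rng.integers(radius_range[0], radius_range[1] + 1))
            b = int(rng.integers(radius_range[0], radius_range[1] + 1))
            r, c = _lesion_center(rng, n, max(a, b) + 1, params)
            rr, cc = draw_ellipse(r, c, a, b, shape=(n, n))
            m[rr, cc] = 1
        masks[lesion] = m

    ma = np.zeros((n, n), dtype=np.uint8)
    count = int(rng.integers(params.ma_count[0], params.ma_count[1] + 1))
    for _ in range(count):
        size = int(rng.integers(params.ma_size[0], params.ma_size[1] + 1))
        r, c = _lesion_center(rng, n, 2, params)
        for dr, dc in _DOT_OFFSETS[size]:
            ma[r + dr, c + dc] = 1
    masks["ma"] = ma

    grade = int(rng.choice(len(params.grade_probs), p=params.grade_probs))
    return LesionMaskSet(
        he=masks["he"], ma=masks["ma"], se=masks["se"], ex=masks["ex"], grade=grade
    )


def generate_corpus(
    params: FixtureParams, n_images: int, seed: int
) -> list[LesionMaskSet]:
    """Independent mask sets from child seeds of one root seed."""
    if n_images < 1:
        raise ValueError(f"n_images must be >= 1, got {n_images}")
    children = np.random.SeedSequence(seed).spawn(n_images)
    return [generate_mask_set(params, np.random.default_rng(c)) for c in children]


def generate_heatmap_with_overlap(
    masks: LesionMaskSet,
    grid: GridSpec,
    k: int,
    q: float,
    w: WeightSet,
    seed: int | np.random.Generator,
    noise: float = 0.0,
) -> Heatmap:
    """Heatmap whose top-K cells contain exactly ``round(q*k)`` expert top cells.

    Construction runs in discretized cell space: ``round(q*k)`` cells
    are drawn from the expert top-K and ``k - round(q*k)`` from outside
    it, the chosen K cells receive distinct large masses (painted as
    cell-constant pixel values scaled by cell area so the discretized
    cell mass is exact), and all other cells receive strictly smaller
    background mass.  The resulting ECS at this (grid, k) equals
    ``round(q*k)/k`` exactly.

    ``noise`` adds uniform per-cell mass perturbations up to
    ``noise * (mean painted cell mass)``; the painted/background margin
    is wider than the largest possible noise differential, so the
    constructed score is unchanged at noise levels up to ~13%.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = grid.grid_size

    de = discretize_expert(masks, w, grid)
    expert_ranked = ranked_cells(de)
    if len(expert_ranked) < k:
        raise InfeasibleOverlapError(
            f"expert discretization has only {len(expert_ranked)} positive cells "
            f"but k={k}; overlap fraction q={q} cannot be constructed"
        )
    expert_top = expert_ranked[:k]

    n_overlap = int(round(q * k))
    n_out = k - n_overlap
    outside = [
        (i, j) for i in range(s) for j in range(s) if (i, j) not in set(expert_top)
    ]
    if len(outside) < n_out:
        raise InfeasibleOverlapError(
            f"grid has only {len(outside)} cells outside the expert top-{k}; "
            f"cannot place {n_out} non-overlapping top cells"
        )
    overlap_idx = rng.choice(k, size=n_overlap, replace=False)
    chosen = [expert_top[i] for i in sorted(overlap_idx)]
    out_idx = rng.choice(len(outside), size=n_out, replace=False)
    chosen += [outside[i] for i in sorted(out_idx)]
    rng.shuffle(chosen)

    # painted cells: masses 2.0 down to 1.0; background strictly below 0.8
    cell_mass = np.asarray(rng.uniform(0.0, 0.8, size=(s, s)))
    for rank, (i, j) in enumerate(chosen):
        cell_mass[i, j] = 2.0 - rank / max(k - 1, 1)
    if noise > 0:
        cell_mass = cell_mass + rng.uniform(0.0, noise * 1.5, size=(s, s))

    heat = np.zeros(grid.image_shape, dtype=float)
    areas = grid.cell_areas()
    for i in range(s):
        for j in range(s):
            sl = grid.cell_slices(i, j)
            heat[sl] = cell_mass[i, j] / areas[i, j]
    return Heatmap(heat)


def toy_scorer(kind: str, params: dict | None = None) -> ScoreFunction:
    """Closed-form score functions with analytic gradients.

    ``kind="linear"``: f(x) = Σ w*x, grad = w (params: ``weights``).
    ``kind="disk-sum"``: total intensity inside a disk, grad = disk
    indicator (params: ``center``, ``radius``, ``shape``).
    ``kind="quadratic"``: f(x) = Σ c*x², grad = 2*c*x (params:
    optional ``coeffs``, default 1).
    """
    params = dict(params or {})
    if kind == "linear":
        w = np.asarray(params["weights"], dtype=float)
        return ScoreFunction(
            f=lambda x: float((w * x).sum()),
            grad=lambda x: np.broadcast_to(w, np.shape(x)).astype(float).copy(),
        )
    if kind == "disk-sum":
        shape = tuple(params["shape"])
        indicator = np.zeros(shape, dtype=float)
        rr, cc = draw_disk(tuple(params["center"]), float(params["radius"]), shape=shape)
        indicator[rr, cc] = 1.0
        return ScoreFunction(
            f=lambda x: float((indicator * x).sum()),
            grad=lambda x: indicator.copy(),
        )
    if kind == "quadratic":
        c = np.asarray(params.get("coeffs", 1.0), dtype=float)
        return ScoreFunction(
            f=lambda x: float((c * np.asarray(x) ** 2).sum()),
            grad=lambda x: 2.0 * c * np.asarray(x, dtype=float),
        )
    raise ValueError(f"unknown scorer kind {kind!r}; use 'linear', 'disk-sum' or 'quadratic'")
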