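"""Grid discretization of lesion segmentations and attribution heatmaps.

The agreement statistic implemented by this package compares an expert
lesion annotation and a model attribution map at the resolution of an
S x S grid overlaid on the image.  This module provides the grid
geometry (:class:`GridSpec`), the in-memory containers for the inputs
(:class:`LesionMaskSet`, :class:`Heatmap`) and outputs
(:class:`DiscretizedMap`), and the three discretization operations:

* :func:`reduce_channels` — collapse a three-channel attribution map to
  a single nonnegative channel (max over channels);
* :func:`discretize_heatmap` — per-cell sums of heatmap values;
* :func:`discretize_expert` — per-cell lesion-pixel counts, weighted by
  lesion type to counter the severe pixel-count imbalance between
  hemorrhages, microaneurysms and exudates.

Cells are 0-based, row-major, and cover half-open pixel blocks
``[i*d, (i+1)*d) x [j*d, (j+1)*d)`` with ``d = N // S``.  When ``N`` is
not divisible by ``S`` the trailing remainder rows/columns are merged
into the last cell row/column, so no annotated pixel is ever dropped.
Rectangular images use independent cell heights and widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "LESION_TYPES",
    "GridSpec",
    "LesionMaskSet",
    "Heatmap",
    "DiscretizedMap",
    "reduce_channels",
    "discretize_heatmap",
    "discretize_expert",
]

#: Canonical lesion-type keys: hemorrhages, microaneurysms, soft
#: exudates, hard exudates (IDRiD annotation convention).
LESION_TYPES: tuple[str, ...] = ("he", "ma", "se", "ex")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the S x S discretization grid.

    Parameters
    ----------
    image_shape
        ``(rows, cols)`` of the images the grid is laid over.
    grid_size
        Number of cells per side, ``S``.

    Notes
    -----
    Cell ``(i, j)`` covers pixel rows ``[i*dy, (i+1)*dy)`` and columns
    ``[j*dx, (j+1)*dx)`` (half-open, 0-based) with ``dy = rows // S``
    and ``dx = cols // S``; the last cell row/column absorbs any
    remainder pixels.
    """

    image_shape: tuple[int, int]
    grid_size: int

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        s = self.grid_size
        if s < 1:
            raise ValueError(f"grid_size must be >= 1, got {s}")
        if min(rows, cols) < s:
            raise ValueError(
                f"image shape {self.image_shape} smaller than grid size {s}; "
                "need at least one pixel per cell"
            )

    @classmethod
    def square(cls, image_size: int, grid_size: int) -> "GridSpec":
        """Grid over an ``image_size`` x ``image_size`` image."""
        return cls((int(image_size), int(image_size)), int(grid_size))

    @property
    def cell_height(self) -> int:
        return self.image_shape[0] // self.grid_size

    @property
    def cell_width(self) -> int:
        return self.image_shape[1] // self.grid_size

    def row_starts(self) -> np.ndarray:
        """Pixel row offsets where each cell row begins."""
        return np.arange(self.grid_size) * self.cell_height

    def col_starts(self) -> np.ndarray:
        return np.arange(self.grid_size) * self.cell_width

    def cell_slices(self, i: int, j: int) -> tuple[slice, slice]:
        """Pixel block covered by cell ``(i, j)``."""
        s = self.grid_size
        rows, cols = self.image_shape
        dy, dx = self.cell_height, self.cell_width
        r1 = rows if i == s - 1 else (i + 1) * dy
        c1 = cols if j == s - 1 else (j + 1) * dx
        return slice(i * dy, r1), slice(j * dx, c1)

    def cell_areas(self) -> np.ndarray:
        """S x S matrix of pixel counts per cell (boundary cells may be larger)."""
        rows, cols = self.image_shape
        dy, dx = self.cell_height, self.cell_width
        h = np.full(self.grid_size, dy, dtype=np.int64)
        w = np.full(self.grid_size, dx, dtype=np.int64)
        h[-1] += rows - dy * self.grid_size
        w[-1] += cols - dx * self.grid_size
        return np.outer(h, w)


def _as_binary_mask(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"mask '{name}' must be strictly binary (0/1)")
    return a.astype(np.uint8, copy=False)


@dataclass
class LesionMaskSet:
    """Four aligned binary lesion masks for one fundus image.

    ``he``/``ma``/``se``/``ex`` are hemorrhage, microaneurysm, soft
    exudate and hard exudate masks of identical shape; masks may
    overlap.  ``grade`` is the optional ordinal DR severity (0-4).
    """

    he: np.ndarray
    ma: np.ndarray
    se: np.ndarray
    ex: np.ndarray
    grade: int | None = None

    def __post_init__(self) -> None:
        self.he = _as_binary_mask(self.he, "he")
        self.ma = _as_binary_mask(self.ma, "ma")
        self.se = _as_binary_mask(self.se, "se")
        self.ex = _as_binary_mask(self.ex, "ex")
        shapes = {m.shape for m in (self.he, self.ma, self.se, self.ex)}
        if len(shapes) != 1:
            raise ValueError(f"lesion masks must share one shape, got {shapes}")
        if self.grade is not None and not 0 <= int(self.grade) <= 4:
            raise ValueError(f"grade must be in 0..4, got {self.grade}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.he.shape

    def mask(self, lesion: str) -> np.ndarray:
        """Return the mask for a lesion type key (``he``/``ma``/``se``/``ex``)."""
        key = lesion.lower()
        if key not in LESION_TYPES:
            raise KeyError(f"unknown lesion type {lesion!r}; expected one of {LESION_TYPES}")
        return getattr(self, key)

    def pixel_counts(self) -> dict[str, int]:
        """Lesion pixels per type in this image."""
        return {t: int(self.mask(t).sum()) for t in LESION_TYPES}


@dataclass
class Heatmap:
    """Single-channel nonnegative importance map, image-shaped."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"heatmap must be 2-D after channel reduction, got ndim={v.ndim}")
        if not np.isfinite(v).all():
            raise ValueError("heatmap contains non-finite values")
        if (v < 0).any():
            raise ValueError("heatmap contains negative values; reduce channels first")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DiscretizedMap:
    """S x S matrix of per-cell mass.

    ``kind`` records whether the cells hold weighted expert lesion
    counts (``"expert"``) or heatmap sums (``"heatmap"``).  Total mass
    is conserved: ``cells.sum()`` equals the (weighted) pixel sum of
    the input.
    """

    cells: np.ndarray
    kind: Literal["expert", "heatmap"]
    grid: GridSpec | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.cells, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"cells must be a square matrix, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("discretized cells must be nonnegative")
        self.cells = c

    @property
    def grid_size(self) -> int:
        return self.cells.shape[0]

    def nnz(self) -> int:
        """Number of cells with strictly positive mass."""
        return int(np.count_nonzero(self.cells > 0))


def block_sum(values: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Sum ``values`` over each grid cell; returns an S x S matrix.

    Implemented with ``np.add.reduceat`` on the cell start offsets, so
    the trailing remainder rows/columns fall into the last cell.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != grid.image_shape:
        raise ValueError(
            f"array shape {v.shape} does not match grid image shape {grid.image_shape}"
        )
    out = np.add.reduceat(v, grid.row_starts(), axis=0)
    out = np.add.reduceat(out, grid.col_starts(), axis=1)
    return out


def reduce_channels(raw: np.ndarray, mode: str = "abs-max") -> Heatmap:
    """Collapse a three-channel attribution map to one channel.

    Parameters
    ----------
    raw
        ``(rows, cols, 3)`` array of finite attribution values.
    mode
        ``"abs-max"`` (default): absolute value per channel, then the
        per-pixel maximum — signed gradient evidence is kept either
        way.  ``"max"``: the literal per-channel maximum, with any
        remaining negative pixels clipped to 0.
    """
    a = np.asarray(raw, dtype=float)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected a (rows, cols, 3) array, got shape {a.shape}")
    if not np.isfinite(a).all():
        raise ValueError("attribution map contains non-finite values")
    if mode == "abs-max":
        reduced = np.abs(a).max(axis=2)
    elif mode == "max":
        reduced = np.clip(a.max(axis=2), 0.0, None)
    else:
        raise ValueError(f"unknown channel-reduction mode {mode!r}; use 'abs-max' or 'max'")
    return Heatmap(reduced)


def discretize_heatmap(h: Heatmap | np.ndarray, grid: GridSpec) -> DiscretizedMap:
    """Per-cell sums of heatmap values (no weighting)."""
    values = h.values if isinstance(h, Heatmap) else Heatmap(np.asarray(h)).values
    return DiscretizedMap(block_sum(values, grid), kind="heatmap", grid=grid)


def discretize_expert(masks: LesionMaskSet, weights, grid: GridSpec) -> DiscretizedMap:
    """Weighted per-cell lesion-pixel counts.

    Each cell holds ``w_HE * #HE + w_MA * #MA + w_SE * #SE + w_EX * #EX``
    over its pixel block, where the weights counter the corpus-level
    pixel-count imbalance between lesion types (see
    :mod:`lesionecs.weights`).
    """
    if masks.shape != grid.image_shape:
        raise ValueError(
            f"mask shape {masks.shape} does not match grid image shape {grid.image_shape}"
        )
    # weighted pixel image first, one block sum after: same summation path as
    # heatmap discretization, so a heatmap equal to the weighted mask
    # combination discretizes bit-identically to the expert map
    weighted = np.zeros(masks.shape, dtype=float)
    for lesion in LESION_TYPES:
        w = weights[lesion] if isinstance(weights, dict) else getattr(weights, f"w_{lesion}")
        weighted += float(w) * masks.mask(lesion)
    return DiscretizedMap(block_sum(weighted, grid), kind="expert", grid=grid)
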