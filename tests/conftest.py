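import numpy as np
import pytest

from lesionecs import FixtureParams, GridSpec, LesionMaskSet, get_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid10():
    return GridSpec.square(128, 10)


@pytest.fixture
def paper_weights():
    return get_preset("idrid-paper")


@pytest.fixture
def default_params():
    return FixtureParams()


def single_pixel_maskset(shape, lesion, at, grade=None):
    """Mask set with exactly one lesion pixel of the given type."""
    masks = {t: np.zeros(shape, dtype=np.uint8) for t in ("he", "ma", "se", "ex")}
    masks[lesion][at] = 1
    return LesionMaskSet(grade=grade, **masks)


# --- independent oracles ------------------------------------------------

def block_sum_oracle(values, grid):
    """Naive double-loop block summation."""
    s = grid.grid_size
    out = np.zeros((s, s))
    for i in range(s):
        for j in range(s):
            sl = grid.cell_slices(i, j)
            out[i, j] = values[sl].sum()
    return out


def top_k_oracle(cells, k):
    """Explicit sort by (value desc, row-major index asc), positive cells only."""
    s = cells.shape[1]
    entries = [
        (-cells[i, j], i * s + j, (i, j))
        for i in range(cells.shape[0])
        for j in range(cells.shape[1])
        if cells[i, j] > 0
    ]
    entries.sort()
    return {cell for _, _, cell in entries[:k]}


def ecs_oracle(de_cells, dh_cells, k):
    """Brute-force ECS by enumeration with the documented tie-break."""
    nnz = int((de_cells > 0).sum())
    expert = top_k_oracle(de_cells, k)
    heat = top_k_oracle(dh_cells, k)
    return len(expert & heat) / min(k, nnz)
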