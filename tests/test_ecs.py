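import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionecs import (
    EmptyExpertError,
    GridSpec,
    discretize_heatmap,
    ecs_per_lesion,
    ecs_score,
    random_baseline,
    top_k_cells,
)

from conftest import ecs_oracle, single_pixel_maskset, top_k_oracle


class TestTopKCells:
    def test_sorted_by_value(self):
        cells = np.array([[3.0, 1.0], [2.0, 0.0]])
        assert top_k_cells(cells, 2) == {(0, 0), (1, 0)}

    def test_all_zero_gives_empty_set(self):
        assert top_k_cells(np.zeros((3, 3)), 5) == set()

    def test_row_major_tie_break(self):
        cells = np.zeros((3, 3))
        for cell in [(0, 1), (1, 0), (1, 2), (2, 0), (2, 2)]:
            cells[cell] = 1.0
        assert top_k_cells(cells, 3) == {(0, 1), (1, 0), (1, 2)}

    def test_fewer_positive_than_k(self):
        cells = np.zeros((3, 3))
        cells[1, 1] = 5.0
        assert top_k_cells(cells, 4) == {(1, 1)}

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            top_k_cells(np.ones((2, 2)), 0)

    def test_random_tie_break_is_seeded(self):
        cells = np.ones((4, 4))
        a = top_k_cells(cells, 5, tie_break="random", rng=np.random.default_rng(0))
        b = top_k_cells(cells, 5, tie_break="random", rng=np.random.default_rng(0))
        c = top_k_cells(cells, 5, tie_break="random", rng=np.random.default_rng(1))
        assert a == b and len(c) == 5


class TestEcsScore:
    def test_identical_maps_score_one(self, rng):
        cells = rng.uniform(0.1, 1.0, size=(5, 5))
        assert ecs_score(cells, cells.copy(), 10).score == 1.0

    def test_disjoint_top_sets_score_zero(self):
        de = np.zeros((4, 4))
        dh = np.zeros((4, 4))
        de[0, :2] = 1.0
        dh[3, :2] = 1.0
        assert ecs_score(de, dh, 2).score == 0.0

    def test_eleven_of_fifteen(self, rng):
        # expert with >= 15 positive cells, heatmap sharing exactly 11 top cells
        de = np.zeros((10, 10))
        expert_cells = [(i, j) for i in range(4) for j in range(4)]  # 16 positive
        for rank, cell in enumerate(expert_cells):
            de[cell] = 100.0 - rank
        top15 = expert_cells[:15]
        dh = np.zeros((10, 10))
        for cell in top15[:11]:
            dh[cell] = rng.uniform(50, 100)
        filler = [(9, j) for j in range(4)]
        for cell in filler:
            dh[cell] = rng.uniform(50, 100)
        res = ecs_score(de, dh, 15)
        assert res.overlap == 11 and res.denominator == 15
        assert res.score == pytest.approx(11 / 15)

    def test_denominator_capped_by_nnz(self):
        de = np.zeros((5, 5))
        for cell in [(0, 0), (1, 1), (2, 2), (3, 3)]:
            de[cell] = 1.0
        dh = de + np.random.default_rng(0).uniform(0, 0.1, size=(5, 5))
        res = ecs_score(de, dh, 15)
        assert res.denominator == 4
        assert res.score == 1.0

    def test_empty_expert_raises(self):
        with pytest.raises(EmptyExpertError):
            ecs_score(np.zeros((3, 3)), np.ones((3, 3)), 2)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ecs_score(np.ones((3, 3)), np.ones((4, 4)), 2)

    def test_rank_invariance_under_monotone_transform(self, rng):
        de = rng.uniform(size=(6, 6))
        dh = rng.uniform(size=(6, 6))
        base = ecs_score(de, dh, 7)
        for f in (lambda x: 3.0 * x, lambda x: x**2, np.sqrt):
            assert ecs_score(de, f(dh), 7).score == base.score

    def test_swapping_in_expert_cell_raises_score_by_unit(self, rng):
        de = rng.uniform(0.1, 1.0, size=(5, 5))
        k = 4
        expert_top = sorted(top_k_oracle(de, k))
        dh = np.zeros((5, 5))
        # heatmap top-k fully disjoint from expert top-k
        others = [c for c in np.ndindex(5, 5) if tuple(c) not in set(expert_top)]
        for rank, cell in enumerate(others[:k]):
            dh[cell] = 10.0 - rank
        s0 = ecs_score(de, dh, k)
        dh[others[0]] = 0.0
        dh[expert_top[0]] = 10.0
        s1 = ecs_score(de, dh, k)
        assert s1.score - s0.score == pytest.approx(1.0 / s0.denominator)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(2, 5), st.integers(1, 4), st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, s, k, seed):
        g = np.random.default_rng(seed)
        de = np.round(g.uniform(0, 1, size=(s, s)) * g.integers(0, 2, size=(s, s)), 2)
        dh = np.round(g.uniform(0, 1, size=(s, s)), 2)
        if (de > 0).sum() == 0:
            de[0, 0] = 1.0
        assert ecs_score(de, dh, k).score == ecs_oracle(de, dh, k)


class TestEcsPerLesion:
    def test_heatmap_from_ma_mask_scores_one(self, rng):
        masks = single_pixel_maskset((64, 64), "ma", (10, 17))
        masks.he[:] = rng.integers(0, 2, size=(64, 64))  # other lesions irrelevant
        grid = GridSpec.square(64, 8)
        dh = discretize_heatmap(masks.ma.astype(float), grid)
        assert ecs_per_lesion(masks, dh, 5, "ma", grid).score == 1.0

    def test_empty_lesion_mask_is_skip_signal(self, grid10):
        masks = single_pixel_maskset((128, 128), "he", (3, 3))
        dh = discretize_heatmap(np.ones((128, 128)), grid10)
        with pytest.raises(EmptyExpertError):
            ecs_per_lesion(masks, dh, 15, "se", grid10)

    def test_equals_ecs_on_single_lesion_map(self, rng, grid10):
        masks = single_pixel_maskset((128, 128), "ex", (60, 60))
        masks.ex[rng.integers(0, 128, 30), rng.integers(0, 128, 30)] = 1
        heat = rng.uniform(size=(128, 128))
        dh = discretize_heatmap(heat, grid10)
        direct = ecs_score(
            discretize_heatmap(masks.ex.astype(float), grid10).cells, dh.cells, 15
        )
        assert ecs_per_lesion(masks, dh, 15, "ex", grid10).score == direct.score


class TestRandomBaseline:
    def test_full_grid_matches_hypergeometric_expectation(self):
        # all 100 cells positive, K=15: E[overlap] = 15*15/100, score E = 0.15
        de = np.random.default_rng(5).uniform(0.1, 1.0, size=(10, 10))
        res = random_baseline(de, 15, n_draws=4000, seed=11)
        assert abs(res.mean - 0.15) <= 3 * res.se

    def test_expert_covering_whole_grid_with_k_cells(self):
        de = np.random.default_rng(2).uniform(0.1, 1.0, size=(3, 3))
        res = random_baseline(de, 9, n_draws=50, seed=0)
        assert res.mean == 1.0

    def test_same_seed_reproducible(self):
        de = np.random.default_rng(3).uniform(size=(6, 6))
        a = random_baseline(de, 5, n_draws=200, seed=42)
        b = random_baseline(de, 5, n_draws=200, seed=42)
        assert (a.mean, a.se) == (b.mean, b.se)
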