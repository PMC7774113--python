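import numpy as np
import pandas as pd
import pytest

from lesionecs import (
    EvalRecord,
    FixtureParams,
    GridSpec,
    bootstrap_ci,
    generate_heatmap_with_overlap,
    generate_mask_set,
    get_preset,
    mean_ecs,
    rank_methods,
    sensitivity_sweep,
    stratify_by_grade,
)
from lesionecs.stats import validate_score_table


def make_table(scores, grades=None, method="m", model="net"):
    n = len(scores)
    return pd.DataFrame(
        {
            "image_id": [f"im{i}" for i in range(n)],
            "model": model,
            "method": method,
            "S": 10,
            "K": 15,
            "score": scores,
            "grade": grades if grades is not None else [None] * n,
        }
    )


class TestMeanEcs:
    def test_simple_mean(self):
        assert mean_ecs(make_table([0.4, 0.6]), None) == pytest.approx(0.5)

    def test_single_score_is_itself(self):
        assert mean_ecs(make_table([0.73]), None) == pytest.approx(0.73)

    def test_grouped_matches_direct_sum(self, rng):
        scores = rng.uniform(size=100)
        t = pd.concat([make_table(scores[:50], method="a"), make_table(scores[50:], method="b")])
        m = mean_ecs(t, ("method",))
        assert m["a"] == pytest.approx(scores[:50].sum() / 50)
        assert m["b"] == pytest.approx(scores[50:].sum() / 50)

    def test_permutation_invariant_and_bounded(self, rng):
        scores = rng.uniform(size=30)
        a = mean_ecs(make_table(scores), None)
        b = mean_ecs(make_table(scores[::-1]), None)
        assert a == pytest.approx(b)
        assert scores.min() <= a <= scores.max()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            mean_ecs(make_table([]), None)


class TestBootstrapCi:
    def test_constant_scores_degenerate_interval(self):
        assert bootstrap_ci([0.5] * 10) == (0.5, 0.5)

    def test_same_seed_identical(self, rng):
        x = rng.uniform(size=40)
        assert bootstrap_ci(x, seed=7) == bootstrap_ci(x, seed=7)

    def test_fewer_than_two_scores_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([0.5])

    def test_coverage_on_uniform_draws(self):
        # 0.5 is the true mean of uniform(0,1); percentile bootstrap at n=200
        # should cover it in >= 90% of repetitions
        hits = 0
        reps = 100
        for rep in range(reps):
            x = np.random.default_rng(1000 + rep).uniform(size=200)
            lo, hi = bootstrap_ci(x, n_boot=800, seed=rep)
            hits += lo <= 0.5 <= hi
        assert hits >= 0.90 * reps

    def test_width_shrinks_like_root_n(self):
        widths = {}
        for n in (25, 100, 400):
            w = []
            for rep in range(20):
                x = np.random.default_rng(n * 37 + rep).uniform(size=n)
                lo, hi = bootstrap_ci(x, n_boot=1000, seed=rep)
                w.append(hi - lo)
            widths[n] = np.mean(w)
        assert widths[100] / widths[25] == pytest.approx(0.5, abs=0.12)
        assert widths[400] / widths[100] == pytest.approx(0.5, abs=0.12)


class TestStratifyByGrade:
    def test_singleton_stratum_has_no_ci(self):
        t = make_table([0.4, 0.6, 0.8], grades=[2, 2, 3])
        out = stratify_by_grade(t).set_index("grade")
        assert out.loc[2, "mean"] == pytest.approx(0.5)
        assert out.loc[3, "mean"] == pytest.approx(0.8)
        assert np.isfinite(out.loc[2, "ci_low"])
        assert np.isnan(out.loc[3, "ci_low"])

    def test_single_grade_equals_overall_mean(self, rng):
        scores = rng.uniform(size=20)
        t = make_table(scores, grades=[4] * 20)
        out = stratify_by_grade(t)
        assert len(out) == 1
        assert out.loc[0, "mean"] == pytest.approx(scores.mean())

    def test_matches_group_then_mean_oracle(self, rng):
        scores = rng.uniform(size=60)
        grades = rng.integers(2, 5, size=60)
        t = make_table(scores, grades=grades)
        out = stratify_by_grade(t).set_index("grade")
        for g in np.unique(grades):
            assert out.loc[g, "mean"] == pytest.approx(scores[grades == g].mean())
            assert out.loc[g, "n"] == int((grades == g).sum())


@pytest.fixture(scope="module")
def fixture_records():
    w = get_preset("idrid-paper")
    params = FixtureParams()
    records = []
    children = np.random.SeedSequence(99).spawn(12)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        masks = generate_mask_set(params, rng)
        grid = GridSpec.square(128, 10)
        q = 0.8 if i % 2 == 0 else 0.2
        heat = generate_heatmap_with_overlap(masks, grid, 15, q, w, rng)
        records.append(
            EvalRecord(f"im{i}", masks, heat, model="synth", method=f"q{q}")
        )
    return records, w


class TestSensitivitySweep:

    def test_perfect_fixture_scores_one_everywhere(self, paper_weights):
        from lesionecs import discretize_expert, Heatmap

        masks = generate_mask_set(FixtureParams(), 4)
        # heatmap = weighted expert mask combination at pixel level
        pix = sum(
            getattr(paper_weights, f"w_{t}") * masks.mask(t).astype(float)
            for t in ("he", "ma", "se", "ex")
        )
        rec = EvalRecord("im0", masks, Heatmap(pix))
        table = sensitivity_sweep([rec], [5, 10], [10, 15, 20], paper_weights)
        assert (table["score"] == 1.0).all()

    def test_k_exceeding_cells_stays_bounded(self, paper_weights):
        masks = generate_mask_set(FixtureParams(image_size=64), 5)
        rec = EvalRecord("im0", masks, np.random.default_rng(0).uniform(size=(64, 64)))
        table = sensitivity_sweep([rec], [4], [100], paper_weights)
        assert ((table["score"] >= 0) & (table["score"] <= 1)).all()
        assert (table["denominator"] <= 16).all()

    def test_construction_target_recovered_across_k(self, fixture_records):
        records, w = fixture_records
        table = sensitivity_sweep(records, [10], [15], w)
        high = table[table["method"] == "q0.8"]["score"].mean()
        low = table[table["method"] == "q0.2"]["score"].mean()
        assert high == pytest.approx(12 / 15)
        assert low == pytest.approx(3 / 15)

    def test_method_ranking_stable_across_k(self, fixture_records):
        records, w = fixture_records
        table = sensitivity_sweep(records, [10], [10, 15, 20], w)
        ranks = rank_methods(table)
        orders = {ranks[(10, k)] for k in (10, 15, 20)}
        assert len(orders) == 1
        assert next(iter(orders))[0] == "q0.8"

    def test_empty_record_list_rejected(self, paper_weights):
        with pytest.raises(ValueError):
            sensitivity_sweep([], [10], [15], paper_weights)


def test_validate_score_table_catches_violations():
    t = make_table([0.5, 1.2])
    with pytest.raises(ValueError):
        validate_score_table(t)
    t2 = pd.concat([make_table([0.5]), make_table([0.6])])
    with pytest.raises(ValueError):
        validate_score_table(t2)


def test_disjoint_fixture_sets_have_overlapping_cis():
    """Two corpora from the same generator settings behave like a tuning/test
    split: their mean-score CIs overlap (stability, not overfitting)."""
    w = get_preset("idrid-paper")
    params = FixtureParams()
    grid = GridSpec.square(128, 10)

    def corpus_scores(seed, n):
        out = []
        for child in np.random.SeedSequence(seed).spawn(n):
            rng = np.random.default_rng(child)
            masks = generate_mask_set(params, rng)
            heat = generate_heatmap_with_overlap(
                masks, grid, 15, 0.5, w, rng, noise=0.1
            )
            rec = EvalRecord("x", masks, heat)
            out.append(
                sensitivity_sweep([rec], [10], [15], w)["score"].iloc[0]
            )
        return np.array(out)

    a = corpus_scores(1, 25)
    b = corpus_scores(2, 25)
    lo_a, hi_a = bootstrap_ci(a, n_boot=2000, seed=0)
    lo_b, hi_b = bootstrap_ci(b, n_boot=2000, seed=0)
    assert max(lo_a, lo_b) <= min(hi_a, hi_b)
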