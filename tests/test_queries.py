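from __future__ import annotations


import numpy as np
import pytest

from alseg.core_types import ImageSample, make_pool
from alseg.features import FeatureMatrix
from alseg.queries import (
    borda_combine,
    cluster_query,
    cwe_mcd_query,
    random_query,
    representative_cwe_mcd_query,
    representative_query,
    representativeness_scores,
)
from alseg.testing import ConstantSegmenter
from conftest import flat_sample, gradient_sample


def pool_of_points(points, labeled=(), size=3):
    """A pool whose images are constant-intensity, one intensity per point."""
    samples = [
        ImageSample(id=f"p{i:02d}", pixels=np.full((size, size), v))
        for i, v in enumerate(points)
    ]
    return make_pool(samples, labeled_ids=[f"p{i:02d}" for i in labeled])


class TestRandomQuery:
    def test_exhaustive_draw_returns_all_unlabeled(self, ten_sample_pool):
        res = random_query(ten_sample_pool, n=20, seed=0)
        assert set(res.selected_ids) == ten_sample_pool.unlabeled_ids

    def test_fixed_seed_reproducible(self, ten_sample_pool):
        a = random_query(ten_sample_pool, 3, seed=7)
        b = random_query(ten_sample_pool, 3, seed=7)
        assert a.selected_ids == b.selected_ids

    def test_selection_frequencies_uniform(self):
        pool = make_pool([flat_sample(f"s{i}") for i in range(10)])
        counts = {sid: 0 for sid in pool.unlabeled_ids}
        reps = 10_000
        for r in range(reps):
            for sid in random_query(pool, 2, seed=r).selected_ids:
                counts[sid] += 1
        # each id is a binomial(reps, 0.2) draw; stay within 3 sigma
        expected = reps * 0.2
        sigma = np.sqrt(reps * 0.2 * 0.8)
        for sid, c in counts.items():
            assert abs(c - expected) < 3 * sigma, sid

    def test_rejects_empty_unlabeled_pool(self):
        pool = make_pool([flat_sample("a")], labeled_ids=["a"])
        with pytest.raises(ValueError, match="empty"):
            random_query(pool, 1, seed=0)


class TestClusterQuery:
    def test_pool_of_exactly_n_returns_all(self):
        pool = pool_of_points([0.1, 0.5, 0.9])
        res = cluster_query(pool, 3, seed=0)
        assert set(res.selected_ids) == pool.unlabeled_ids

    def test_duplicate_points_collapse_to_one_per_group(self):
        pool = pool_of_points([0.2] * 4 + [0.8] * 4)
        res = cluster_query(pool, 2, seed=0)
        values = sorted(float(pool.sample(s).pixels[0, 0]) for s in res.selected_ids)
        assert values == [0.2, 0.8]

    def test_one_member_per_well_separated_group(self, rng):
        centers = [0.1, 0.4, 0.7]
        values, groups = [], []
        for gi, c in enumerate(centers):
            for _ in range(5):
                values.append(c + rng.uniform(-0.02, 0.02))
                groups.append(gi)
        pool = pool_of_points(values)
        res = cluster_query(pool, 3, seed=1)
        # brute-force group assignment of each selected id by nearest center
        chosen_groups = sorted(
            int(np.argmin([abs(pool.sample(s).pixels[0, 0] - c) for c in centers]))
            for s in res.selected_ids
        )
        assert chosen_groups == [0, 1, 2]

    def test_oversized_n_returns_whole_pool(self):
        pool = pool_of_points([0.1, 0.6])
        assert set(cluster_query(pool, 5, seed=0).selected_ids) == pool.unlabeled_ids


class TestRepresentativenessScores:
    def test_coincident_centroids_give_zero(self):
        u = FeatureMatrix(np.array([[1.0, 0.0], [-1.0, 0.0]]), ("a", "b"), "reduced")
        l = FeatureMatrix(np.array([[2.0, 0.0], [-2.0, 0.0]]), ("c", "d"), "reduced")
        scores = representativeness_scores(u, l).scores
        # both centroids at the origin -> d(x, mu_L) == d(x, mu_U) for all x
        assert all(v == pytest.approx(0.0) for v in scores.values())

    def test_point_at_unlabeled_centroid(self):
        u = FeatureMatrix(np.array([[3.0, 0.0]]), ("x",), "reduced")
        l = FeatureMatrix(np.array([[0.0, 0.0]]), ("l",), "reduced")
        assert representativeness_scores(u, l).scores["x"] == pytest.approx(3.0)

    def test_hand_computed_line_example(self):
        # L = {(0,0)}, U = {(2,0),(4,0)}: mu_L=(0,0), mu_U=(3,0)
        u = FeatureMatrix(np.array([[2.0, 0.0], [4.0, 0.0]]), ("a", "b"), "reduced")
        l = FeatureMatrix(np.array([[0.0, 0.0]]), ("l",), "reduced")
        scores = representativeness_scores(u, l).scores
        assert scores["a"] == pytest.approx(2.0 - 1.0)
        assert scores["b"] == pytest.approx(4.0 - 1.0)

    def test_rejects_empty_labeled(self):
        u = FeatureMatrix(np.array([[1.0]]), ("a",), "reduced")
        l = FeatureMatrix(np.empty((0, 1)), (), "reduced")
        with pytest.raises(ValueError, match="empty"):
            representativeness_scores(u, l)


class TestRepresentativeQuery:
    def test_farthest_from_labeled_wins_line_example(self):
        # labeled at low intensity; unlabeled at higher intensities
        pool = pool_of_points([0.0, 0.5, 0.9], labeled=[0])
        res = representative_query(pool, 1)
        assert res.selected_ids == ("p02",)

    def test_total_tie_breaks_by_stable_order(self):
        pool = pool_of_points([0.1, 0.7, 0.7, 0.7], labeled=[0])
        res = representative_query(pool, 2)
        assert res.selected_ids == ("p01", "p02")

    def test_matches_argsort_oracle_on_random_pools(self, rng):
        samples = [gradient_sample(f"g{i:02d}", float(rng.uniform(0, 0.4))) for i in range(20)]
        pool = make_pool(samples, labeled_ids=["g00", "g01", "g02"])
        res = representative_query(pool, 5)
        scores = res.scores
        stable = [s.id for s in pool.unlabeled_samples()]
        oracle = sorted(stable, key=lambda sid: (-scores[sid], stable.index(sid)))[:5]
        assert list(res.selected_ids) == oracle

    def test_rejects_empty_labeled_partition(self):
        pool = pool_of_points([0.1, 0.9])
        with pytest.raises(ValueError, match="labeled"):
            representative_query(pool, 1)


class TestCweMcdQuery:
    def test_half_probability_sample_is_most_uncertain(self):
        pool = make_pool([flat_sample("a"), flat_sample("b"), flat_sample("c")])
        model = ConstantSegmenter(probabilities={"a": 1.0, "b": 0.5, "c": 0.9})
        res = cwe_mcd_query(pool, 1, model, k=5, seed=0)
        assert res.selected_ids == ("b",)

    def test_deterministic_model_matches_single_pass_ranking(self):
        pool = make_pool([flat_sample(f"s{i}") for i in range(4)])
        probs = {"s0": 0.9, "s1": 0.45, "s2": 0.2, "s3": 0.65}
        model = ConstantSegmenter(probabilities=probs, noise_scale=0.0)
        res = cwe_mcd_query(pool, 4, model, k=7, seed=3)
        def lit_entropy(p):
            return -p * np.log2(p) if p > 0 else 0.0
        oracle = sorted(probs, key=lambda s: -lit_entropy(probs[s]))
        assert list(res.selected_ids) == oracle

    def test_matches_argsort_oracle_with_stochastic_stub(self, rng):
        pool = make_pool([flat_sample(f"s{i}") for i in range(12)])
        probs = {f"s{i}": float(rng.uniform(0.05, 0.95)) for i in range(12)}
        model = ConstantSegmenter(probabilities=probs, noise_scale=0.05)
        res = cwe_mcd_query(pool, 5, model, k=10, seed=21)
        stable = [s.id for s in pool.unlabeled_samples()]
        oracle = sorted(res.scores, key=lambda sid: (-res.scores[sid], stable.index(sid)))[:5]
        assert list(res.selected_ids) == oracle

    def test_untrained_model_rejected(self):
        from alseg.synthetic_data import reference_segmenter
        pool = make_pool([flat_sample("a")])
        with pytest.raises(RuntimeError, match="untrained"):
            cwe_mcd_query(pool, 1, reference_segmenter(seed=0), k=2, seed=0)


def brute_force_borda(score_maps, stable_ids):
    """Exhaustive Borda points with tie sharing, by explicit enumeration."""
    combined = {sid: 0.0 for sid in stable_ids}
    for m in score_maps:
        for sid in stable_ids:
            beats = sum(1 for other in stable_ids if m[other] < m[sid])
            ties = sum(1 for other in stable_ids if other != sid and m[other] == m[sid])
            combined[sid] += beats + ties / 2.0
    return combined


class TestBordaCombine:
    def test_identical_rankings_preserve_order(self):
        scores = {"a": 3.0, "b": 2.0, "c": 1.0}
        ranking = borda_combine(scores, dict(scores), stable_ids=["a", "b", "c"])
        assert ranking.ordering == ("a", "b", "c")

    def test_hand_computed_two_criterion_example(self):
        r = {"id1": 1.0, "id2": 2.0, "id3": 3.0}
        e = {"id1": 3.0, "id2": 1.0, "id3": 2.0}
        ranking = borda_combine(r, e, stable_ids=["id1", "id2", "id3"])
        assert ranking.points_per_criterion[0] == {"id1": 0.0, "id2": 1.0, "id3": 2.0}
        assert ranking.points_per_criterion[1] == {"id1": 2.0, "id2": 0.0, "id3": 1.0}
        assert ranking.combined == {"id1": 2.0, "id2": 1.0, "id3": 3.0}
        assert ranking.ordering == ("id3", "id1", "id2")

    def test_reversed_rankings_tie_and_break_by_stable_order(self):
        r = {"a": 1.0, "b": 2.0, "c": 3.0}
        e = {"a": 3.0, "b": 2.0, "c": 1.0}
        ranking = borda_combine(r, e, stable_ids=["a", "b", "c"])
        assert len(set(ranking.combined.values())) == 1
        assert ranking.ordering == ("a", "b", "c")

    def test_invariant_to_criterion_order_and_monotone_transform(self, rng):
        ids = [f"i{j}" for j in range(8)]
        r = {sid: float(rng.normal()) for sid in ids}
        e = {sid: float(rng.normal()) for sid in ids}
        base = borda_combine(r, e, stable_ids=ids)
        swapped = borda_combine(e, r, stable_ids=ids)
        squashed = borda_combine({s: np.tanh(v) for s, v in r.items()}, e, stable_ids=ids)
        assert base.ordering == swapped.ordering
        assert base.ordering == squashed.ordering

    def test_matches_exhaustive_enumeration_with_ties(self, rng):
        for trial in range(20):
            ids = [f"i{j}" for j in range(6)]
            r = {sid: float(rng.integers(0, 4)) for sid in ids}  # many ties
            e = {sid: float(rng.integers(0, 4)) for sid in ids}
            ranking = borda_combine(r, e, stable_ids=ids)
            assert ranking.combined == pytest.approx(brute_force_borda([r, e], ids))

    def test_rejects_mismatched_id_sets(self):
        with pytest.raises(ValueError, match="symmetric difference"):
            borda_combine({"a": 1.0}, {"b": 1.0})


class TestRepresentativeCweMcdQuery:
    def test_agreeing_rankings_match_single_criterion_query(self):
        # intensity order equals entropy order: constant prob = pixel value,
        # all below 1/e where -p log2 p is still increasing
        values = [0.10, 0.15, 0.20, 0.25]
        pool = pool_of_points(values + [0.05], labeled=[4])
        model = ConstantSegmenter(
            probabilities={f"p{i:02d}": v for i, v in enumerate(values)}
        )
        fused = representative_cwe_mcd_query(pool, 2, model, k=3, seed=0)
        rep = representative_query(pool, 2)
        assert set(fused.selected_ids) == set(rep.selected_ids)

    def test_matches_brute_force_borda_on_small_pool(self, rng):
        samples = [gradient_sample(f"g{i}", float(rng.uniform(0, 0.4))) for i in range(6)]
        pool = make_pool(samples, labeled_ids=["g0"])
        probs = {f"g{i}": float(rng.uniform(0.1, 0.9)) for i in range(1, 6)}
        model = ConstantSegmenter(probabilities=probs)
        res = representative_cwe_mcd_query(pool, 3, model, k=4, seed=9)
        r_scores = representative_query(pool, 5).scores
        from alseg.uncertainty import class_wise_entropy, mc_ensemble, mean_prediction
        ens = mc_ensemble(model, pool.unlabeled_samples(), k=4, seed=9)
        e_scores = class_wise_entropy(mean_prediction(ens)).scores
        combined = brute_force_borda([r_scores, e_scores], [s.id for s in pool.unlabeled_samples()])
        stable = [s.id for s in pool.unlabeled_samples()]
        oracle = sorted(stable, key=lambda sid: (-combined[sid], stable.index(sid)))[:3]
        assert list(res.selected_ids) == oracle


@pytest.mark.parametrize("n", [1, 3, 8, 15])
def test_every_query_returns_distinct_unlabeled_ids(n, rng):
    samples = [gradient_sample(f"g{i:02d}", float(rng.uniform(0, 0.4))) for i in range(14)]
    pool = make_pool(samples, labeled_ids=["g00", "g01"])
    model = ConstantSegmenter(
        probabilities={s.id: float(rng.uniform(0.1, 0.9)) for s in samples},
        noise_scale=0.02,
    )
    expected = min(n, pool.n_unlabeled)
    for res in (
        random_query(pool, n, seed=1),
        cluster_query(pool, n, seed=1),
        representative_query(pool, n),
        cwe_mcd_query(pool, n, model, k=3, seed=1),
        representative_cwe_mcd_query(pool, n, model, k=3, seed=1),
    ):
        assert len(res.selected_ids) == expected
        assert len(set(res.selected_ids)) == expected
        assert set(res.selected_ids) <= pool.unlabeled_ids
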