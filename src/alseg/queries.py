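"""The five acquisition strategies.

Each query maps (pool, batch size n, context) to a :class:`QueryResult` of
min(n, |U|) distinct unlabeled ids:

- ``random``: uniform draw without replacement — the baseline.
- ``cluster``: flatten → min-max normalize → PCA(99%) → K-Means++ with
  k = n clusters → the pool element nearest each centroid (diversity).
- ``representative``: R(x) = d(x, μ_L) - d(x, μ_U) in the shared reduced
  space — high R is typical of the unlabeled pool yet far from the current
  training data.
- ``cwe_mcd``: class-wise entropy of the Monte Carlo Dropout mean
  prediction (uncertainty).
- ``representative_cwe_mcd``: Borda-count fusion of the R and entropy
  rankings.

All ties break by stable (pool input) id order so selections are
deterministic; seeded queries are bit-reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .core_types import Pool, QueryResult, SegmenterContract
from .features import FeatureMatrix, reduce_features
from .uncertainty import EntropyVariant, class_wise_entropy, mc_ensemble, mean_prediction


@dataclass(frozen=True)
class RepresentativenessScores:
    """Per-id representativeness R = d(x, μ_labeled) - d(x, μ_unlabeled)."""

    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        for sid, v in self.scores.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite representativeness for {sid!r}")


@dataclass(frozen=True)
class BordaRanking:
    """Borda points per criterion, their sum, and the final ordering.

    Within one criterion the best of m ids receives m-1 points down to 0;
    ties share the mean of their point block. Combined points are the sum
    over criteria; the final ordering is by descending combined points with
    ties broken by stable id order.
    """

    points_per_criterion: tuple[dict[str, float], ...]
    combined: dict[str, float]
    ordering: tuple[str, ...]


def _stable_top_ids(
    scores: Mapping[str, float], stable_ids: Sequence[str], n: int
) -> list[str]:
    """Top-n ids by descending score; ties keep stable (input) order."""
    order = {sid: i for i, sid in enumerate(stable_ids)}
    ranked = sorted(scores, key=lambda sid: (-scores[sid], order[sid]))
    return ranked[:n]


def random_query(pool: Pool, n: int, seed: int = 0) -> QueryResult:
    """Uniformly sample min(n, |U|) unlabeled ids without replacement."""
    if n < 1:
        raise ValueError("n must be >= 1")
    unlabeled = [s.id for s in pool.unlabeled_samples()]
    if not unlabeled:
        raise ValueError("unlabeled pool is empty")
    t0 = time.perf_counter()
    rng = np.random.default_rng(seed)
    take = min(n, len(unlabeled))
    chosen = rng.choice(len(unlabeled), size=take, replace=False)
    selected = tuple(unlabeled[i] for i in chosen)
    return QueryResult(
        selected_ids=selected,
        query_name="random",
        elapsed_seconds=time.perf_counter() - t0,
    )


def _nearest_per_centroid(
    centroids: np.ndarray, points: np.ndarray, ids: Sequence[str]
) -> list[str]:
    """Assign each centroid its nearest unused point, greedily by distance.

    When two centroids share a nearest element the globally closest
    (centroid, element) pairs win first and each element is used once, so
    the result is always k distinct ids.
    """
    d = np.linalg.norm(centroids[:, None, :] - points[None, :, :], axis=2)
    pairs = sorted(
        ((d[c, e], c, e) for c in range(d.shape[0]) for e in range(d.shape[1])),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_c: set[int] = set()
    used_e: set[int] = set()
    chosen: dict[int, int] = {}
    for _, c, e in pairs:
        if c in used_c or e in used_e:
            continue
        chosen[c] = e
        used_c.add(c)
        used_e.add(e)
        if len(chosen) == d.shape[0]:
            break
    return [ids[chosen[c]] for c in sorted(chosen)]


def cluster_query(
    pool: Pool,
    n: int,
    seed: int = 0,
    thumbnail_size: tuple[int, int] | None = None,
    target_variance: float = 0.99,
) -> QueryResult:
    """Diversity sampling: one element per K-Means++ cluster of the reduced pool.

    The unlabeled images are flattened, min-max normalized, PCA-reduced at
    the target explained variance, clustered into min(n, |U|) groups with
    K-Means++, and the pool element nearest each centroid is selected.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unlabeled = pool.unlabeled_samples()
    if not unlabeled:
        raise ValueError("unlabeled pool is empty")
    t0 = time.perf_counter()
    take = min(n, len(unlabeled))
    if take == len(unlabeled):
        ids = tuple(s.id for s in unlabeled)
        return QueryResult(ids, "cluster", time.perf_counter() - t0)
    reduced = reduce_features(unlabeled, thumbnail_size, target_variance)
    n_distinct = np.unique(reduced.rows, axis=0).shape[0]
    km = KMeans(
        n_clusters=min(take, n_distinct),
        init="k-means++",
        n_init=10,
        random_state=seed % (2**32),
    ).fit(reduced.rows)
    selected = _nearest_per_centroid(km.cluster_centers_, reduced.rows, reduced.ids)
    if len(selected) < take:
        # fewer distinct points than clusters: fill with unused ids in stable order
        unused = [sid for sid in reduced.ids if sid not in set(selected)]
        selected += unused[: take - len(selected)]
    return QueryResult(tuple(selected), "cluster", time.perf_counter() - t0)


def representativeness_scores(
    reduced_unlabeled: FeatureMatrix, reduced_labeled: FeatureMatrix
) -> RepresentativenessScores:
    """R(x) = ||x - μ_labeled|| - ||x - μ_unlabeled|| for each unlabeled x.

    Both matrices must live in the same reduced space. The cluster
    centroids μ are arithmetic means (a one-cluster K-Means fixed point is
    the mean, so no iterative fit is needed). High R marks samples typical
    of the unlabeled population but unlike the current training data.
    """
    if reduced_labeled.n == 0:
        raise ValueError("labeled feature matrix is empty")
    if reduced_unlabeled.dim != reduced_labeled.dim:
        raise ValueError("labeled and unlabeled features must share one basis")
    mu_l = reduced_labeled.rows.mean(axis=0)
    mu_u = reduced_unlabeled.rows.mean(axis=0)
    d_l = np.linalg.norm(reduced_unlabeled.rows - mu_l, axis=1)
    d_u = np.linalg.norm(reduced_unlabeled.rows - mu_u, axis=1)
    return RepresentativenessScores(
        scores={sid: float(r) for sid, r in zip(reduced_unlabeled.ids, d_l - d_u)}
    )


def _pool_representativeness(
    pool: Pool,
    thumbnail_size: tuple[int, int] | None,
    target_variance: float,
) -> RepresentativenessScores:
    """Compute R over the unlabeled pool in a basis fit on U ∪ L."""
    labeled = pool.labeled_samples()
    unlabeled = pool.unlabeled_samples()
    if not labeled:
        raise ValueError("representative query needs a non-empty labeled partition")
    if not unlabeled:
        raise ValueError("unlabeled pool is empty")
    everything = unlabeled + labeled
    reduced_all = reduce_features(
        everything, thumbnail_size, target_variance, fit_samples=everything
    )
    n_u = len(unlabeled)
    red_u = FeatureMatrix(reduced_all.rows[:n_u], reduced_all.ids[:n_u], "reduced")
    red_l = FeatureMatrix(reduced_all.rows[n_u:], reduced_all.ids[n_u:], "reduced")
    return representativeness_scores(red_u, red_l)


def representative_query(
    pool: Pool,
    n: int,
    thumbnail_size: tuple[int, int] | None = None,
    target_variance: float = 0.99,
) -> QueryResult:
    """Select the min(n, |U|) unlabeled ids with the highest R values."""
    if n < 1:
        raise ValueError("n must be >= 1")
    t0 = time.perf_counter()
    r = _pool_representativeness(pool, thumbnail_size, target_variance)
    stable = [s.id for s in pool.unlabeled_samples()]
    selected = _stable_top_ids(r.scores, stable, min(n, len(stable)))
    return QueryResult(
        tuple(selected), "representative", time.perf_counter() - t0, scores=dict(r.scores)
    )


def cwe_mcd_query(
    pool: Pool,
    n: int,
    model: SegmenterContract,
    k: int = 30,
    seed: int = 0,
    entropy_variant: EntropyVariant = "literal",
) -> QueryResult:
    """Uncertainty sampling: highest class-wise entropy of the MCD mean.

    Runs k dropout-active forward passes over the unlabeled pool, averages
    them, scores each sample with class-wise Shannon entropy and takes the
    top min(n, |U|).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unlabeled = pool.unlabeled_samples()
    if not unlabeled:
        raise ValueError("unlabeled pool is empty")
    t0 = time.perf_counter()
    ens = mc_ensemble(model, unlabeled, k=k, seed=seed)
    scores = class_wise_entropy(mean_prediction(ens), variant=entropy_variant).scores
    stable = [s.id for s in unlabeled]
    selected = _stable_top_ids(scores, stable, min(n, len(stable)))
    return QueryResult(
        tuple(selected), "cwe_mcd", time.perf_counter() - t0, scores=dict(scores)
    )


def borda_combine(
    *score_maps: Mapping[str, float], stable_ids: Sequence[str] | None = None
) -> BordaRanking:
    """Fuse several higher-is-better score maps by Borda count.

    Every map must cover the same id set. Per criterion, ids are ranked and
    awarded m-1 (best) down to 0 points, tied ids sharing the mean of their
    point block; combined points are summed across criteria. The ordering
    is by descending combined points, ties broken by ``stable_ids`` order
    (sorted ids when not given).
    """
    if not score_maps:
        raise ValueError("need at least one score map")
    id_sets = [set(m) for m in score_maps]
    base = id_sets[0]
    for other in id_sets[1:]:
        if other != base:
            diff = sorted(base ^ other)
            raise ValueError(f"score maps cover different ids; symmetric difference {diff}")
    ids = list(stable_ids) if stable_ids is not None else sorted(base)
    if set(ids) != base:
        raise ValueError("stable_ids must cover exactly the scored ids")

    per_criterion: list[dict[str, float]] = []
    for m in score_maps:
        vals = np.array([m[sid] for sid in ids], dtype=np.float64)
        # ascending average rank 1..m  ->  points rank-1 (higher score = more)
        pts = rankdata(vals, method="average") - 1.0
        per_criterion.append({sid: float(p) for sid, p in zip(ids, pts)})
    combined = {sid: sum(pc[sid] for pc in per_criterion) for sid in ids}
    order = {sid: i for i, sid in enumerate(ids)}
    ordering = tuple(sorted(ids, key=lambda sid: (-combined[sid], order[sid])))
    return BordaRanking(
        points_per_criterion=tuple(per_criterion), combined=combined, ordering=ordering
    )


def representative_cwe_mcd_query(
    pool: Pool,
    n: int,
    model: SegmenterContract,
    k: int = 30,
    seed: int = 0,
    thumbnail_size: tuple[int, int] | None = None,
    target_variance: float = 0.99,
    entropy_variant: EntropyVariant = "literal",
) -> QueryResult:
    """Borda-count fusion of the representativeness and entropy rankings.

    R and the class-wise MCD entropy are computed separately over the
    unlabeled pool, each ranking is converted to Borda points, and the
    min(n, |U|) ids with the highest combined points are selected.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unlabeled = pool.unlabeled_samples()
    if not unlabeled:
        raise ValueError("unlabeled pool is empty")
    t0 = time.perf_counter()
    r = _pool_representativeness(pool, thumbnail_size, target_variance)
    ens = mc_ensemble(model, unlabeled, k=k, seed=seed)
    e = class_wise_entropy(mean_prediction(ens), variant=entropy_variant).scores
    stable = [s.id for s in unlabeled]
    ranking = borda_combine(r.scores, e, stable_ids=stable)
    selected = ranking.ordering[: min(n, len(stable))]
    return QueryResult(
        tuple(selected),
        "representative_cwe_mcd",
        time.perf_counter() - t0,
        scores=dict(ranking.combined),
    )


#: registry for CLI / config selection by name
QUERY_REGISTRY = {
    "random": random_query,
    "cluster": cluster_query,
    "representative": representative_query,
    "cwe_mcd": cwe_mcd_query,
    "representative_cwe_mcd": representative_cwe_mcd_query,
}
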