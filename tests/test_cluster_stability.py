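import itertools
import math

import numpy as np
import pytest

from genostab import (
    Embedding,
    ParameterError,
    fowlkes_mallows,
    kmeans_cluster,
    optimal_k,
    pairwise_cluster_similarity,
    pandora_cluster_stability,
)


def fm_brute_force(a, b):
    """Pair-enumeration Fowlkes-Mallows oracle."""
    tp = fp = fn = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        tp += same_a and same_b
        fp += same_a and not same_b
        fn += same_b and not same_a
    if tp == 0:
        return 0.0
    return tp / math.sqrt((tp + fp) * (tp + fn))


def blob_embedding(k_true, per_blob=10, spread=0.05, seed=0, rotate=None):
    """Well-separated Gaussian blobs on a circle of radius 10."""
    rng = np.random.default_rng(seed)
    centers = 10.0 * np.stack(
        [
            np.cos(2 * np.pi * np.arange(k_true) / k_true),
            np.sin(2 * np.pi * np.arange(k_true) / k_true),
        ],
        axis=1,
    )
    coords = np.vstack(
        [c + spread * rng.normal(size=(per_blob, 2)) for c in centers]
    )
    if rotate is not None:
        rot = np.array(
            [[np.cos(rotate), -np.sin(rotate)], [np.sin(rotate), np.cos(rotate)]]
        )
        coords = coords @ rot
    labels_true = np.repeat(np.arange(k_true), per_blob)
    emb = Embedding(
        coords=coords, row_labels=[f"ind_{i}" for i in range(len(coords))]
    )
    return emb, labels_true


class TestFowlkesMallows:
    def test_identical_partitions_score_one(self):
        assert fowlkes_mallows([0, 0, 1, 1, 2], [5, 5, 3, 3, 9]) == pytest.approx(1.0)

    def test_crossed_partitions_score_zero(self):
        # {1,2},{3,4} vs {1,3},{2,4}: no pair co-clustered in both
        assert fowlkes_mallows([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_partial_overlap_hand_case(self):
        # {1,2,3},{4} vs {1,2},{3,4}: TP=1, FP=2, FN=1 -> 1/sqrt(6)
        assert fowlkes_mallows([0, 0, 0, 1], [0, 0, 1, 1]) == pytest.approx(
            1 / math.sqrt(6)
        )

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        a = rng.integers(0, 4, size=n)
        b = rng.integers(0, 4, size=n)
        assert fowlkes_mallows(a, b) == pytest.approx(fm_brute_force(a, b), abs=1e-12)

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(3)
        a, b = rng.integers(0, 3, 12), rng.integers(0, 3, 12)
        assert fowlkes_mallows(a, b) == pytest.approx(fowlkes_mallows(b, a))
        relabel = np.array([2, 0, 1])
        assert fowlkes_mallows(relabel[a], b) == pytest.approx(fowlkes_mallows(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            fowlkes_mallows([0, 1], [0, 1, 2])


class TestKMeans:
    def test_recovers_separated_triplets(self):
        emb, truth = blob_embedding(k_true=3, per_blob=3, spread=0.01, seed=1)
        res = kmeans_cluster(emb, k=3, seed=0)
        assert fowlkes_mallows(res.labels, truth) == pytest.approx(1.0)

    def test_k_equal_rows_gives_zero_inertia(self):
        emb, _ = blob_embedding(k_true=2, per_blob=2, seed=2)
        res = kmeans_cluster(emb, k=4, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(set(res.labels.tolist())) == 4

    def test_deterministic_given_seed(self):
        emb, _ = blob_embedding(k_true=3, per_blob=6, spread=1.0, seed=3)
        a = kmeans_cluster(emb, k=3, seed=42).labels
        b = kmeans_cluster(emb, k=3, seed=42).labels
        assert np.array_equal(a, b)

    def test_k_out_of_range_rejected(self):
        emb, _ = blob_embedding(k_true=2, per_blob=2, seed=1)
        with pytest.raises(ParameterError):
            kmeans_cluster(emb, k=5)


class TestOptimalK:
    @pytest.mark.parametrize("k_true", [3, 4, 5])
    def test_recovers_true_blob_count(self, k_true):
        emb, _ = blob_embedding(k_true=k_true, per_blob=12, spread=0.1, seed=k_true)
        assert optimal_k(emb, seed=0) == k_true

    def test_population_labels_bound_the_search(self):
        # 8 true blobs but only 5 distinct population labels: k must stay <= 5
        emb, _ = blob_embedding(k_true=8, per_blob=10, spread=0.1, seed=6)
        pops = [f"pop_{i % 5}" for i in range(emb.n_rows)]
        assert 3 <= optimal_k(emb, populations=pops, seed=0) <= 5

    def test_sqrt_bound_without_populations(self):
        # 100 rows, no labels: search range is [3, ceil(sqrt(100))] = [3, 10]
        emb, _ = blob_embedding(k_true=4, per_blob=25, spread=0.1, seed=7)
        assert optimal_k(emb, seed=0) == 4

    def test_too_few_rows_instructs_manual_k(self):
        emb = Embedding(coords=np.eye(2), row_labels=["a", "b"])
        with pytest.raises(ParameterError, match="manually"):
            optimal_k(emb)


class TestPairwisePCS:
    def test_identical_embeddings_same_seed_score_one(self):
        emb, _ = blob_embedding(k_true=3, per_blob=8, spread=0.5, seed=8)
        assert pairwise_cluster_similarity(
            emb, emb, k=3, seed=1, indices=(0, 0)
        ) == pytest.approx(1.0)

    def test_rotation_removed_before_clustering(self):
        emb, _ = blob_embedding(k_true=3, per_blob=8, spread=0.05, seed=9)
        rotated, _ = blob_embedding(
            k_true=3, per_blob=8, spread=0.05, seed=9, rotate=2.1
        )
        assert pairwise_cluster_similarity(
            emb, rotated, k=3, seed=1, indices=(0, 1)
        ) == pytest.approx(1.0)

    def test_value_in_unit_interval(self):
        rng = np.random.default_rng(10)
        emb_u = Embedding(coords=rng.normal(size=(12, 2)), row_labels=[str(i) for i in range(12)])
        emb_v = Embedding(coords=rng.normal(size=(12, 2)), row_labels=[str(i) for i in range(12)])
        score = pairwise_cluster_similarity(emb_u, emb_v, k=3, seed=0)
        assert 0.0 <= score <= 1.0


class TestOverallPCS:
    def test_identical_embeddings_score_one(self):
        emb, _ = blob_embedding(k_true=3, per_blob=8, spread=0.3, seed=11)
        pcs, k = pandora_cluster_stability([emb] * 4, k=3, seed=0)
        assert pcs == pytest.approx(1.0)
        assert k == 3

    def test_equals_mean_of_pairwise_scores(self):
        embs = [blob_embedding(k_true=3, per_blob=6, spread=1.5, seed=s)[0] for s in (1, 2, 3)]
        pcs, _ = pandora_cluster_stability(embs, k=3, seed=5)
        expected = np.mean(
            [
                pairwise_cluster_similarity(embs[u], embs[v], k=3, seed=5, indices=(u, v))
                for u, v in itertools.combinations(range(3), 2)
            ]
        )
        assert pcs == pytest.approx(expected, abs=1e-12)

    def test_decreases_with_blob_overlap(self):
        def mean_pcs(spread):
            vals = []
            for seed in range(5):
                embs = [
                    blob_embedding(k_true=3, per_blob=8, spread=spread, seed=100 * seed + r)[0]
                    for r in range(3)
                ]
                vals.append(pandora_cluster_stability(embs, k=3, seed=seed)[0])
            return np.mean(vals)

        assert mean_pcs(0.2) > mean_pcs(6.0)

    def test_requires_two_embeddings(self):
        emb, _ = blob_embedding(k_true=3, per_blob=4, seed=1)
        with pytest.raises(ValueError):
            pandora_cluster_stability([emb], k=3)
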