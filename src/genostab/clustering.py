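"""Cluster stability (PCS) across bootstrap embeddings.

For each pair of bootstrap embeddings, one is Procrustes-matched onto the
other, both are clustered independently with k-means using the same k, and
the agreement of the two label vectors is scored with the Fowlkes–Mallows
index. The overall PCS is the mean of these pairwise scores. When k is not
given it is chosen by a BIC grid search between 3 and the number of distinct
populations (or sqrt of the number of rows when no labels exist).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import fowlkes_mallows_score

from .embedding import Embedding, ParameterError
from .procrustes import procrustes_transform


@dataclass
class ClusteringResult:
    labels: np.ndarray  # R integers in [0, k)
    k: int
    inertia: float  # within-cluster sum of squares


def _derive_seed(seed: int, index: int) -> int:
    """Deterministic child seed, kept below 2**31."""
    return (int(seed) * 1_000_003 + int(index) * 7919 + 1) % (2**31)


def fowlkes_mallows(labels_a, labels_b) -> float:
    """Fowlkes–Mallows agreement of two partitions, in [0, 1].

    FM = TP / sqrt((TP+FP)(TP+FN)) over all unordered item pairs, where TP
    counts pairs co-clustered in both partitions. Invariant to permuting the
    cluster ids of either partition.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape or labels_a.ndim != 1:
        raise ParameterError("label vectors must be 1-D and of equal length")
    if labels_a.size < 2:
        raise ParameterError("need at least 2 items")
    return float(fowlkes_mallows_score(labels_a, labels_b))


def kmeans_cluster(embedding: Embedding, k: int, seed: int = 0) -> ClusteringResult:
    """Hard k-means labels (k-means++ init, 10 restarts, seed-deterministic)."""
    r = embedding.n_rows
    if not 2 <= k <= r:
        raise ParameterError(f"k={k} must be in [2, R] = [2, {r}]")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    labels = km.fit_predict(embedding.coords)
    return ClusteringResult(labels=labels, k=k, inertia=float(km.inertia_))


def _bic(result: ClusteringResult, r: int, d: int) -> float:
    """BIC under a spherical Gaussian mixture with shared variance.

    Free parameters p = k (D + 1); sigma^2 estimated as inertia/(D (R - k)).
    """
    k = result.k
    sigma2 = result.inertia / (d * max(r - k, 1))
    sigma2 = max(sigma2, 1e-12)
    counts = np.bincount(result.labels, minlength=k)
    counts = counts[counts > 0]
    log_lik = (
        float((counts * np.log(counts / r)).sum())
        - r * d / 2.0 * np.log(2.0 * np.pi * sigma2)
        - (r - k) * d / 2.0
    )
    p = k * (d + 1)
    return p * np.log(r) - 2.0 * log_lik


def optimal_k(
    embedding: Embedding,
    populations: list[str] | None = None,
    k_min: int = 3,
    k_max: int | None = None,
    seed: int = 0,
) -> int:
    """BIC grid search for the number of k-means clusters.

    The upper bound defaults to the number of distinct non-empty population
    labels when available, otherwise ceil(sqrt(R)); the lower bound is 3.
    Ties go to the smallest k.
    """
    r = embedding.n_rows
    if r < k_min:
        raise ParameterError(
            f"only {r} rows but k_min={k_min}; set k manually for this dataset"
        )
    if populations is None:
        populations = embedding.populations
    if k_max is None:
        distinct = {p for p in (populations or []) if p}
        k_max = len(distinct) if len(distinct) >= 2 else int(np.ceil(np.sqrt(r)))
    k_max = min(max(k_max, k_min), r)
    best_k, best_bic = k_min, np.inf
    for k in range(k_min, k_max + 1):
        bic = _bic(kmeans_cluster(embedding, k, seed=_derive_seed(seed, k)), r,
                   embedding.n_components)
        if bic < best_bic:
            best_k, best_bic = k, bic
    return best_k


def pairwise_cluster_similarity(
    p_u: Embedding,
    p_v: Embedding,
    k: int,
    seed: int = 0,
    indices: tuple[int, int] = (0, 1),
) -> float:
    """Fowlkes–Mallows agreement of k-means labels of a matched pair.

    ``p_u`` is Procrustes-matched onto ``p_v`` first; each side is then
    clustered independently with a seed derived from ``seed`` and its
    replicate index, so results are reproducible.
    """
    aligned_u, b, _ = procrustes_transform(p_u, p_v)
    emb_u = Embedding(coords=aligned_u, row_labels=list(p_u.row_labels))
    emb_v = Embedding(coords=b, row_labels=list(p_v.row_labels))
    labels_u = kmeans_cluster(emb_u, k, seed=_derive_seed(seed, indices[0])).labels
    labels_v = kmeans_cluster(emb_v, k, seed=_derive_seed(seed, indices[1])).labels
    return fowlkes_mallows(labels_u, labels_v)


def pandora_cluster_stability(
    embeddings: list[Embedding],
    k: int | None = None,
    seed: int = 0,
    populations: list[str] | None = None,
) -> tuple[float, int]:
    """Mean pairwise cluster similarity (PCS) and the k that was used.

    When ``k`` is None it is chosen once by :func:`optimal_k` on the first
    embedding and reused for every pair.
    """
    n = len(embeddings)
    if n < 2:
        raise ValueError("at least 2 embeddings are required")
    if k is None:
        k = optimal_k(embeddings[0], populations=populations, seed=seed)
    scores = [
        pairwise_cluster_similarity(
            embeddings[u], embeddings[v], k, seed=seed, indices=(u, v)
        )
        for u, v in itertools.combinations(range(n), 2)
    ]
    return float(np.mean(scores)), k


__all__ = [
    "ClusteringResult",
    "fowlkes_mallows",
    "kmeans_cluster",
    "optimal_k",
    "pairwise_cluster_similarity",
    "pandora_cluster_stability",
]
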