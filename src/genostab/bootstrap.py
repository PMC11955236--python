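"""SNP-bootstrap replicates, parallel embedding, and early stopping.

A bootstrap replicate keeps the exact same individuals but resamples the K
SNP columns with replacement, following the phylogenetics convention of
treating loci (not individuals) as the exchangeable units. Replicate
embeddings are computed in parallel batches; once at least 10 replicates
exist, a heuristic convergence check compares the overall stability score
(PS) on random half-size subsets of the completed replicates and stops early
when the relative spread of those subset estimates falls below a tolerance.

Every replicate's seed is derived from the master seed and its index before
dispatch, and the convergence criterion is evaluated at fixed
replicate-count checkpoints on the deterministic replicate sequence, so a
run's result is independent of the number of threads.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .embedding import Embedding, mds_embed, pairwise_distance, pca_embed
from .io import GenotypeDataset
from .procrustes import pairwise_similarity_matrix, procrustes_disparity

logger = logging.getLogger(__name__)

#: convergence checks start once this many replicates are complete
MIN_REPLICATES_FOR_CONVERGENCE = 10


@dataclass
class BootstrapRun:
    embeddings: list[Embedding]
    converged: bool
    n_computed: int


def _derive_seed(master_seed: int, index: int) -> int:
    return (int(master_seed) + int(index)) % (2**31)


def bootstrap_indices(k: int, replicate_seed: int) -> np.ndarray:
    """K SNP indices sampled i.i.d. uniform on [0, K) with replacement."""
    if k < 1:
        raise ValueError("K must be >= 1")
    return np.random.default_rng(replicate_seed).integers(0, k, size=k)


def build_replicate(dataset: GenotypeDataset, indices) -> GenotypeDataset:
    """Gather SNP columns (duplicates allowed); individuals are untouched."""
    indices = np.asarray(indices, dtype=int)
    if indices.min(initial=0) < 0 or indices.max(initial=0) >= dataset.n_snps:
        raise IndexError("bootstrap index out of range")
    return GenotypeDataset(
        dosages=dataset.dosages[:, indices],
        missing_mask=dataset.missing_mask[:, indices],
        individual_ids=list(dataset.individual_ids),
        populations=list(dataset.populations),
        snp_ids=[dataset.snp_ids[j] for j in indices],
        chromosomes=[dataset.chromosomes[j] for j in indices]
        if dataset.chromosomes is not None
        else None,
        positions=dataset.positions[indices] if dataset.positions is not None else None,
    )


def _embed(dataset: GenotypeDataset, method: str, params: dict, seed: int) -> Embedding:
    if method == "pca":
        return pca_embed(
            dataset,
            n_components=params.get("n_components", 10),
            project_ids=params.get("project_ids", ()),
        )
    if method == "mds":
        dist = pairwise_distance(
            dataset,
            metric=params.get("metric", "euclidean"),
            level=params.get("level", "individual"),
        )
        return mds_embed(dist, n_components=params.get("n_components", 2), seed=seed)
    raise ValueError(f"unknown method {method!r}; expected 'pca' or 'mds'")


def _subset_ps(sims: np.ndarray, subset: np.ndarray) -> float:
    block = sims[np.ix_(subset, subset)]
    iu = np.triu_indices(len(subset), k=1)
    return float(block[iu].mean())


def _spread_from_sims(
    sims: np.ndarray, n: int, n_subsets: int, rng: np.random.Generator
) -> float:
    """Relative spread (max-min)/max of PS over random half-size subsets."""
    size = math.ceil(n / 2)
    estimates = [
        _subset_ps(sims, rng.choice(n, size=size, replace=False))
        for _ in range(n_subsets)
    ]
    top = max(estimates)
    if top <= 0:
        return 0.0
    return (top - min(estimates)) / top


def check_convergence(
    embeddings: list[Embedding],
    tolerance: float,
    n_subsets: int = 10,
    seed: int = 0,
) -> bool:
    """True when subset-PS estimates agree to within the relative tolerance.

    Draws ``n_subsets`` random subsets of size ceil(n/2) without replacement
    from the completed replicates, computes PS on each, and declares
    convergence when (max - min)/max <= tolerance.
    """
    n = len(embeddings)
    if n < MIN_REPLICATES_FOR_CONVERGENCE:
        raise ValueError(
            f"convergence check requires >= {MIN_REPLICATES_FOR_CONVERGENCE} embeddings"
        )
    sims = pairwise_similarity_matrix(embeddings)
    rng = np.random.default_rng(seed)
    return _spread_from_sims(sims, n, n_subsets, rng) <= tolerance


def run_bootstrap(
    dataset: GenotypeDataset,
    method: str = "pca",
    method_params: dict | None = None,
    n_max: int = 100,
    tolerance: float = 0.05,
    threads: int = 1,
    master_seed: int = 0,
    disable_convergence: bool = False,
    n_subsets: int = 10,
    fixed_indices: np.ndarray | None = None,
) -> BootstrapRun:
    """Compute bootstrap-replicate embeddings with optional early stopping.

    Replicates are dispatched in batches of ``threads``; after each batch the
    convergence criterion is evaluated at every new replicate-count
    checkpoint m >= 10 on the first m replicates, and on success the run is
    truncated to those m replicates. ``fixed_indices`` overrides the
    resampled SNP indices of every replicate (a hook for deterministic
    integration tests, e.g. identity resampling).
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    # tolerance 0 is unattainable by convention: always compute all n_max
    if tolerance <= 0:
        disable_convergence = True
    params = dict(method_params or {})

    def one_replicate(i: int) -> Embedding:
        seed = _derive_seed(master_seed, i)
        idx = (
            np.asarray(fixed_indices, dtype=int)
            if fixed_indices is not None
            else bootstrap_indices(dataset.n_snps, seed)
        )
        replicate = build_replicate(dataset, idx)
        try:
            return _embed(replicate, method, params, seed)
        except Exception as exc:  # annotate with the replicate number
            raise RuntimeError(f"embedding failed on bootstrap replicate {i}: {exc}") from exc

    embeddings: list[Embedding] = []
    sims = np.eye(0)
    next_checkpoint = MIN_REPLICATES_FOR_CONVERGENCE
    pool = Parallel(n_jobs=max(1, threads), backend="threading")
    while len(embeddings) < n_max:
        batch = range(len(embeddings), min(len(embeddings) + max(1, threads), n_max))
        embeddings.extend(pool(delayed(one_replicate)(i) for i in batch))
        n = len(embeddings)
        if disable_convergence:
            logger.info("bootstrap: %d/%d replicates done", n, n_max)
            continue
        # grow the cached pairwise-similarity matrix
        old = sims.shape[0]
        grown = np.eye(n)
        grown[:old, :old] = sims
        for u, v in itertools.product(range(old), range(old, n)):
            grown[u, v] = grown[v, u] = procrustes_disparity(
                embeddings[u], embeddings[v]
            ).similarity
        for u, v in itertools.combinations(range(old, n), 2):
            grown[u, v] = grown[v, u] = procrustes_disparity(
                embeddings[u], embeddings[v]
            ).similarity
        sims = grown
        while next_checkpoint <= n:
            m = next_checkpoint
            rng = np.random.default_rng(_derive_seed(master_seed, 1_000_000 + m))
            spread = _spread_from_sims(sims[:m, :m], m, n_subsets, rng)
            logger.info(
                "bootstrap: %d/%d replicates done, subset-PS spread %.4f at m=%d",
                n, n_max, spread, m,
            )
            if spread <= tolerance:
                return BootstrapRun(
                    embeddings=embeddings[:m], converged=True, n_computed=m
                )
            next_checkpoint += 1
    return BootstrapRun(embeddings=embeddings, converged=False, n_computed=len(embeddings))
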