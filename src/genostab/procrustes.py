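"""Procrustes comparison of embeddings and the overall stability score (PS).

Two embeddings of the same individuals are compared by first standardizing
each one (centering at the origin and scaling to trace(P P^T) = 1), then
finding the scaling, rotation/reflection and translation of one onto the
other that minimizes the squared Frobenius residual. That residual is the
disparity D in [0, 1]; the pairwise similarity is 1 - D, and the overall
stability PS is the mean pairwise similarity over all unordered pairs of
bootstrap embeddings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.linalg import svd

from .embedding import Embedding


class DegenerateEmbeddingError(ValueError):
    """All points coincide; the embedding cannot be standardized."""


class AlignmentError(ValueError):
    """Embeddings cannot be compared row-by-row (labels differ)."""


@dataclass
class ProcrustesTransform:
    """The optimal map f(P) = scale * P @ rotation + translation.

    Applies to standardized coordinates; after standardization both point
    sets are centered, so the translation component is zero by construction.
    """

    scale: float
    rotation: np.ndarray
    translation: np.ndarray


@dataclass
class SimilarityResult:
    disparity: float
    similarity: float
    transform: ProcrustesTransform


def standardize(embedding: Embedding) -> Embedding:
    """Center the rows at the origin and scale so trace(P P^T) = 1."""
    c = embedding.coords - embedding.coords.mean(axis=0)
    norm = np.sqrt((c**2).sum())
    if norm < 1e-12:
        raise DegenerateEmbeddingError(
            "all points coincide; embedding cannot be standardized"
        )
    return Embedding(
        coords=c / norm,
        row_labels=list(embedding.row_labels),
        level=embedding.level,
        populations=list(embedding.populations) if embedding.populations else None,
    )


def _check_compatible(p_u: Embedding, p_v: Embedding) -> None:
    if p_u.coords.shape != p_v.coords.shape:
        raise AlignmentError(
            f"shape mismatch: {p_u.coords.shape} vs {p_v.coords.shape}"
        )
    if p_u.row_labels != p_v.row_labels:
        for a, b in zip(p_u.row_labels, p_v.row_labels):
            if a != b:
                raise AlignmentError(f"row label mismatch: {a!r} vs {b!r}")
        raise AlignmentError("row labels differ")


def procrustes_transform(p_u: Embedding, p_v: Embedding):
    """Optimal alignment of standardized ``p_u`` onto standardized ``p_v``.

    Returns ``(aligned_u, standardized_v, transform)`` where ``aligned_u`` is
    ``scale * A @ rotation`` for ``A`` the standardized coordinates of
    ``p_u``; the closed form comes from the SVD of A^T B.
    """
    _check_compatible(p_u, p_v)
    a = standardize(p_u).coords
    b = standardize(p_v).coords
    u, s, vt = svd(a.T @ b)
    rot = u @ vt
    scale = float(s.sum())  # trace(A^T A) = 1 after standardization
    aligned = scale * a @ rot
    transform = ProcrustesTransform(
        scale=scale, rotation=rot, translation=np.zeros(a.shape[1])
    )
    return aligned, b, transform


def procrustes_disparity(p_u: Embedding, p_v: Embedding) -> SimilarityResult:
    """Disparity D (minimal squared Frobenius residual) and similarity 1 - D."""
    aligned, b, transform = procrustes_transform(p_u, p_v)
    disparity = float(((aligned - b) ** 2).sum())
    disparity = min(max(disparity, 0.0), 1.0)
    return SimilarityResult(
        disparity=disparity, similarity=1.0 - disparity, transform=transform
    )


def pairwise_similarity_matrix(embeddings: list[Embedding]) -> np.ndarray:
    """Symmetric N x N matrix of pairwise similarities (unit diagonal)."""
    n = len(embeddings)
    sims = np.eye(n)
    for u, v in itertools.combinations(range(n), 2):
        sims[u, v] = sims[v, u] = procrustes_disparity(
            embeddings[u], embeddings[v]
        ).similarity
    return sims


def pandora_stability(embeddings: list[Embedding]) -> float:
    """Mean pairwise Procrustes similarity over all unordered pairs.

    1 means every pair of bootstrap embeddings projects all individuals
    identically (up to scaling, rotation/reflection and translation).
    """
    n = len(embeddings)
    if n < 2:
        raise ValueError("at least 2 embeddings are required")
    sims = pairwise_similarity_matrix(embeddings)
    iu = np.triu_indices(n, k=1)
    return float(sims[iu].mean())
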