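"""Per-row support values (PSVs) across bootstrap embeddings.

The support of one individual (or population) is one minus the Gini
coefficient of its projections across all bootstrap replicates:

    PSV_i = 1 - sum_{u<v} ||x_i^u - x_i^v|| / (N * sum_u ||x_i^u||)

so 1 means the replicates place the row identically and values near 0 flag
"rogue" rows whose placement is unstable. The projections x_i^u are only
comparable in a common frame, so all embeddings are first standardized and
Procrustes-aligned onto the first one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .embedding import Embedding
from .procrustes import procrustes_transform, standardize


@dataclass
class SupportVector:
    """Support values in [0, 1], keyed by embedding row label."""

    values: pd.Series

    def write_tsv(self, path) -> None:
        """Two-column TSV sorted ascending, least stable rows first."""
        out = self.values.sort_values()
        out.rename("psv").to_frame().to_csv(
            path, sep="\t", index_label="row_label", float_format="%.6f"
        )


def align_to_reference(embeddings: list[Embedding]) -> list[Embedding]:
    """Standardize all embeddings and Procrustes-align them onto the first.

    Needed because per-replicate embeddings are only defined up to rotation,
    reflection, scale and translation; without a common frame, arbitrary
    axis flips would dominate the per-row dispersion.
    """
    if len(embeddings) <= 1:
        return list(embeddings)
    reference = standardize(embeddings[0])
    aligned = [reference]
    for emb in embeddings[1:]:
        coords, _, _ = procrustes_transform(emb, reference)
        aligned.append(
            Embedding(
                coords=coords,
                row_labels=list(emb.row_labels),
                level=emb.level,
                populations=list(emb.populations) if emb.populations else None,
            )
        )
    return aligned


def pandora_support_values(aligned_embeddings: list[Embedding]) -> SupportVector:
    """Gini-based support value per row over N aligned embeddings.

    A row projected to the origin by every replicate has an undefined (0/0)
    Gini coefficient and receives support 1 with a warning.
    """
    n = len(aligned_embeddings)
    if n < 2:
        raise ValueError("at least 2 embeddings are required")
    labels = aligned_embeddings[0].row_labels
    for emb in aligned_embeddings[1:]:
        if emb.row_labels != labels:
            raise ValueError("embeddings have mismatched row labels")
    stack = np.stack([emb.coords for emb in aligned_embeddings])  # (N, R, D)
    r = stack.shape[1]
    psv = np.empty(r)
    degenerate = []
    for i in range(r):
        points = stack[:, i, :]
        denom = n * np.linalg.norm(points, axis=1).sum()
        if denom <= 1e-300:
            degenerate.append(labels[i])
            psv[i] = 1.0
            continue
        gini = pdist(points).sum() / denom
        psv[i] = np.clip(1.0 - gini, 0.0, 1.0)
    if degenerate:
        warnings.warn(
            f"rows with all-zero projections assigned support 1: {degenerate[:10]}",
            stacklevel=2,
        )
    return SupportVector(values=pd.Series(psv, index=labels, name="psv"))
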