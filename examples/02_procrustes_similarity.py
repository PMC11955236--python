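"""Compare two embeddings with Procrustes analysis.

Builds an embedding and a rotated + scaled + shifted copy, then a genuinely
different embedding, and prints the disparity (squared Frobenius residual
after removing scale, rotation/reflection and translation) and the
similarity 1 - disparity for both pairs. The transformed copy scores
similarity 1 because the transformation family is exactly what the
alignment removes; the unrelated embedding scores much lower.
"""

import numpy as np

from genostab import Embedding, procrustes_disparity

rng = np.random.default_rng(3)
labels = [f"ind_{i}" for i in range(12)]
base = Embedding(coords=rng.normal(size=(12, 2)), row_labels=labels)

theta = 0.8
rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
copy = Embedding(coords=2.0 * base.coords @ rot + [5.0, -1.0], row_labels=labels)
other = Embedding(coords=rng.normal(size=(12, 2)), row_labels=labels)

for name, emb in [("transformed copy", copy), ("unrelated embedding", other)]:
    res = procrustes_disparity(base, emb)
    print(f"{name:>20}: disparity = {res.disparity:.6f}, similarity = {res.similarity:.6f}")
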