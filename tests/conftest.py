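import numpy as np
import pytest

from genostab import MISSING, Embedding, GenotypeDataset


def make_dataset(seed=0, m=6, k=12, missing_frac=0.0, n_pops=2):
    """Small random genotype dataset for unit tests."""
    rng = np.random.default_rng(seed)
    dosages = rng.integers(0, 3, size=(m, k)).astype(np.int8)
    mask = rng.random((m, k)) < missing_frac
    dosages = np.where(mask, MISSING, dosages)
    pops = [f"pop_{i % n_pops}" for i in range(m)]
    return GenotypeDataset(
        dosages=dosages,
        missing_mask=mask,
        individual_ids=[f"ind_{i}" for i in range(m)],
        populations=pops,
        snp_ids=[f"snp_{s}" for s in range(k)],
    )


def make_embedding(seed=0, r=8, d=2, labels=None):
    rng = np.random.default_rng(seed)
    return Embedding(
        coords=rng.normal(size=(r, d)),
        row_labels=labels or [f"ind_{i}" for i in range(r)],
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def embedding_factory():
    return make_embedding
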