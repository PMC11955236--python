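"""Synthetic structured genotype data and distortion protocols.

Genotypes are drawn from the Balding–Nichols model: each SNP has an
ancestral allele frequency p ~ Uniform(0.05, 0.95); each population draws
its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), whose expected
differentiation from the ancestor is the tunable FST parameter F; diploid
dosages are then Binomial(2, p_pop). This yields clearly structured
multi-population data with a controllable divergence, standing in for
whole-genome demographic simulations.

Two distortion protocols emulate data-quality degradation: replacing a fixed
proportion of cells with the missing code, and flipping a fixed proportion
of non-missing cells to a different genotype code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeDataset, write_eigenstrat


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    divergence_fst is the Balding–Nichols F, the expected allele-frequency
    differentiation of each population from the common ancestral pool.
    """

    n_populations: int = 2
    n_per_population: int = 50
    n_snps: int = 5000
    divergence_fst: float = 0.1
    missing_proportion: float = 0.0
    noise_proportion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.n_per_population < 2:
            raise ValueError("n_per_population must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 < self.divergence_fst < 1.0:
            raise ValueError("divergence_fst must lie in (0, 1)")
        for name in ("missing_proportion", "noise_proportion"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")


def simulate_genotypes(config: SimulationConfig) -> GenotypeDataset:
    """Draw a Balding–Nichols dataset, then apply the configured distortions."""
    rng = np.random.default_rng(config.seed)
    k = config.n_snps
    f = config.divergence_fst
    p_anc = rng.uniform(0.05, 0.95, size=k)
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    blocks = []
    populations = []
    for j in range(config.n_populations):
        p_pop = rng.beta(a, b)
        blocks.append(rng.binomial(2, p_pop, size=(config.n_per_population, k)))
        populations += [f"pop_{j}"] * config.n_per_population
    dosages = np.vstack(blocks).astype(np.int8)
    m = dosages.shape[0]
    ds = GenotypeDataset(
        dosages=dosages,
        missing_mask=np.zeros((m, k), dtype=bool),
        individual_ids=[f"ind_{i}" for i in range(m)],
        populations=populations,
        snp_ids=[f"snp_{s}" for s in range(k)],
    )
    if config.missing_proportion > 0:
        ds = inject_missing(ds, config.missing_proportion, seed=int(rng.integers(2**31)))
    if config.noise_proportion > 0:
        ds = inject_noise(ds, config.noise_proportion, seed=int(rng.integers(2**31)))
    return ds


def inject_missing(dataset: GenotypeDataset, proportion: float, seed: int = 0) -> GenotypeDataset:
    """Replace floor(proportion * M * K) distinct cells with the missing code.

    Cells are chosen uniformly at random over the whole matrix; dimensions
    are unchanged.
    """
    if not 0.0 <= proportion < 1.0:
        raise ValueError("proportion must lie in [0, 1)")
    m, k = dataset.dosages.shape
    n_cells = int(np.floor(proportion * m * k))
    dosages = dataset.dosages.copy()
    mask = dataset.missing_mask.copy()
    if n_cells:
        flat = np.random.default_rng(seed).choice(m * k, size=n_cells, replace=False)
        rows, cols = np.unravel_index(flat, (m, k))
        dosages[rows, cols] = MISSING
        mask[rows, cols] = True
    return GenotypeDataset(
        dosages=dosages,
        missing_mask=mask,
        individual_ids=list(dataset.individual_ids),
        populations=list(dataset.populations),
        snp_ids=list(dataset.snp_ids),
        chromosomes=dataset.chromosomes,
        positions=dataset.positions,
    )


def inject_noise(dataset: GenotypeDataset, proportion: float, seed: int = 0) -> GenotypeDataset:
    """Flip floor(proportion * M * K) distinct observed cells to another code.

    Each altered cell receives a uniformly random genotype in {0, 1, 2}
    different from its current value, so the nominal noise proportion is the
    effective one. Missing cells are never altered.
    """
    if not 0.0 <= proportion < 1.0:
        raise ValueError("proportion must lie in [0, 1)")
    m, k = dataset.dosages.shape
    n_cells = int(np.floor(proportion * m * k))
    dosages = dataset.dosages.copy()
    if n_cells:
        eligible = np.flatnonzero(~dataset.missing_mask.ravel())
        if n_cells > eligible.size:
            raise ValueError(
                f"cannot alter {n_cells} cells: only {eligible.size} observed"
            )
        rng = np.random.default_rng(seed)
        flat = rng.choice(eligible, size=n_cells, replace=False)
        rows, cols = np.unravel_index(flat, (m, k))
        offsets = rng.integers(1, 3, size=n_cells)  # +1 or +2 mod 3 != identity
        dosages[rows, cols] = (dosages[rows, cols] + offsets) % 3
    return GenotypeDataset(
        dosages=dosages,
        missing_mask=dataset.missing_mask.copy(),
        individual_ids=list(dataset.individual_ids),
        populations=list(dataset.populations),
        snp_ids=list(dataset.snp_ids),
        chromosomes=dataset.chromosomes,
        positions=dataset.positions,
    )


def write_fixture(dataset: GenotypeDataset, prefix):
    """Write the dataset as an EIGENSTRAT triplet; returns the file paths."""
    return write_eigenstrat(dataset, prefix)
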