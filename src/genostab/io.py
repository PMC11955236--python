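"""Genotype dataset container and text-format I/O.

Genotypes are biallelic dosages: each entry counts copies (0, 1 or 2) of the
reference allele A at one SNP in one diploid individual; the heterozygous
states aA and Aa share the code 1. A dedicated sentinel (9) marks missing
genotypes. Supported on-disk formats are the EIGENSTRAT text triplet
(.geno/.snp/.ind), the PLINK text pedigree pair (.ped/.map) and generic
delimited numeric matrices.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: sentinel used for missing genotypes, from the EIGENSTRAT text dialect
MISSING = 9

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class GenotypeFormatError(ValueError):
    """Malformed genotype input (inconsistent dimensions or invalid codes)."""


@dataclass
class GenotypeDataset:
    """An M x K matrix of biallelic genotype dosages with metadata.

    Parameters
    ----------
    dosages
        Integer matrix of shape (M individuals, K SNPs) with entries in
        {0, 1, 2}; missing entries hold the sentinel 9 and are flagged in
        ``missing_mask`` (the mask is the authority).
    missing_mask
        Boolean matrix of the same shape; True where the genotype is missing.
    individual_ids
        M unique individual identifiers.
    populations
        M population labels (empty string when unknown).
    snp_ids
        K SNP identifiers.
    chromosomes, positions
        Optional per-SNP chromosome labels and 1-based physical positions.
    """

    dosages: np.ndarray
    missing_mask: np.ndarray
    individual_ids: list[str]
    populations: list[str]
    snp_ids: list[str]
    chromosomes: list[str] | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.dosages.ndim != 2:
            raise GenotypeFormatError("dosages must be a 2-D matrix")
        m, k = self.dosages.shape
        if m < 2 or k < 1:
            raise GenotypeFormatError(
                f"need at least 2 individuals and 1 SNP, got {m} x {k}"
            )
        if self.missing_mask.shape != (m, k):
            raise GenotypeFormatError("missing_mask shape does not match dosages")
        observed = self.dosages[~self.missing_mask]
        if observed.size and not np.isin(observed, (0, 1, 2)).all():
            bad = observed[~np.isin(observed, (0, 1, 2))][0]
            raise GenotypeFormatError(f"non-missing dosage {bad!r} outside {{0,1,2}}")
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.populations = [str(p) for p in self.populations]
        self.snp_ids = [str(s) for s in self.snp_ids]
        if len(self.individual_ids) != m:
            raise GenotypeFormatError("individual_ids length does not match M")
        if len(set(self.individual_ids)) != m:
            raise GenotypeFormatError("individual_ids must be unique")
        if len(self.populations) != m:
            raise GenotypeFormatError("populations length does not match M")
        if len(self.snp_ids) != k:
            raise GenotypeFormatError("snp_ids length does not match K")
        if self.chromosomes is not None and len(self.chromosomes) != k:
            raise GenotypeFormatError("chromosomes length does not match K")
        if self.positions is not None:
            self.positions = np.asarray(self.positions)
            if self.positions.shape != (k,):
                raise GenotypeFormatError("positions length does not match K")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def equals(self, other: "GenotypeDataset") -> bool:
        """Content equality: observed dosages, masks and metadata match."""
        if self.dosages.shape != other.dosages.shape:
            return False
        if not np.array_equal(self.missing_mask, other.missing_mask):
            return False
        obs = ~self.missing_mask
        if not np.array_equal(self.dosages[obs], other.dosages[obs]):
            return False
        return (
            self.individual_ids == other.individual_ids
            and self.populations == other.populations
            and self.snp_ids == other.snp_ids
        )


def read_eigenstrat(geno_path, snp_path, ind_path) -> GenotypeDataset:
    """Read an EIGENSTRAT text triplet.

    The .geno file holds one line per SNP with one character per individual
    in {0,1,2,9}; the .ind file one line per individual (id, sex, population);
    the .snp file one line per SNP.
    """
    ind_lines = [ln.split() for ln in _read_lines(ind_path)]
    individual_ids = [row[0] for row in ind_lines]
    populations = [row[2] if len(row) > 2 else "" for row in ind_lines]
    m = len(ind_lines)

    snp_lines = [ln.split() for ln in _read_lines(snp_path)]
    snp_ids = [row[0] for row in snp_lines]
    chromosomes = [row[1] if len(row) > 1 else "" for row in snp_lines]
    positions = np.array(
        [int(float(row[3])) if len(row) > 3 else i + 1 for i, row in enumerate(snp_lines)]
    )

    geno_lines = _read_lines(geno_path)
    if len(geno_lines) != len(snp_lines):
        raise GenotypeFormatError(
            f"{geno_path}: {len(geno_lines)} genotype lines but "
            f"{len(snp_lines)} SNPs in {snp_path}"
        )
    rows = np.empty((len(geno_lines), m), dtype=np.int8)
    for s, line in enumerate(geno_lines):
        if len(line) != m:
            raise GenotypeFormatError(
                f"{geno_path} line {s + 1}: width {len(line)} != {m} individuals"
            )
        codes = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
        if not np.isin(codes, (0, 1, 2, MISSING)).all():
            bad = line[int(np.argmin(np.isin(codes, (0, 1, 2, MISSING))))]
            raise GenotypeFormatError(
                f"{geno_path} line {s + 1}: invalid genotype character {bad!r}"
            )
        rows[s] = codes
    dosages = rows.T.copy()
    return GenotypeDataset(
        dosages=dosages,
        missing_mask=dosages == MISSING,
        individual_ids=individual_ids,
        populations=populations,
        snp_ids=snp_ids,
        chromosomes=chromosomes,
        positions=positions,
    )


def write_eigenstrat(dataset: GenotypeDataset, prefix) -> tuple[Path, Path, Path]:
    """Write ``dataset`` as ``<prefix>.geno/.snp/.ind``; returns the paths."""
    geno, snp, ind = (Path(f"{prefix}{s}") for s in (".geno", ".snp", ".ind"))
    codes = np.where(dataset.missing_mask, MISSING, dataset.dosages)
    with open(geno, "w") as fh:
        for s in range(dataset.n_snps):
            fh.write("".join(str(int(c)) for c in codes[:, s]) + "\n")
    chroms = dataset.chromosomes or ["1"] * dataset.n_snps
    pos = (
        dataset.positions
        if dataset.positions is not None
        else np.arange(1, dataset.n_snps + 1)
    )
    with open(snp, "w") as fh:
        for s in range(dataset.n_snps):
            fh.write(f"{dataset.snp_ids[s]}\t{chroms[s]}\t0.0\t{int(pos[s])}\n")
    with open(ind, "w") as fh:
        for i in range(dataset.n_individuals):
            pop = dataset.populations[i] or "???"
            fh.write(f"{dataset.individual_ids[i]}\tU\t{pop}\n")
    return geno, snp, ind


def read_plink_ped(ped_path, map_path) -> GenotypeDataset:
    """Read a PLINK text pedigree pair (.ped/.map).

    Each .ped line carries 6 metadata columns (family, individual, paternal,
    maternal, sex, phenotype) followed by 2K allele symbols; "0" marks a
    missing allele. Per SNP the two most frequent observed symbols define the
    biallelic pair and the dosage counts the alphabetically-first of the two,
    so decoding is independent of the allele order within a genotype.
    Genotypes with any missing allele are treated as missing; the family id
    becomes the population label.
    """
    map_rows = [ln.split() for ln in _read_lines(map_path)]
    snp_ids = [row[1] if len(row) > 1 else row[0] for row in map_rows]
    chromosomes = [row[0] for row in map_rows]
    positions = np.array(
        [int(float(row[3])) if len(row) > 3 else i + 1 for i, row in enumerate(map_rows)]
    )
    k = len(map_rows)

    individual_ids: list[str] = []
    populations: list[str] = []
    allele_rows: list[np.ndarray] = []
    for i, line in enumerate(_read_lines(ped_path)):
        tokens = line.split()
        if len(tokens) < 6 or (len(tokens) - 6) % 2 != 0:
            raise GenotypeFormatError(
                f"{ped_path} line {i + 1}: expected 6 metadata columns plus an "
                f"even number of allele columns, got {len(tokens)} tokens"
            )
        if (len(tokens) - 6) // 2 != k:
            raise GenotypeFormatError(
                f"{ped_path} line {i + 1}: {(len(tokens) - 6) // 2} genotypes "
                f"but {k} SNPs in {map_path}"
            )
        populations.append(tokens[0])
        individual_ids.append(tokens[1])
        allele_rows.append(np.array(tokens[6:], dtype=object).reshape(k, 2))
    alleles = np.stack(allele_rows)  # (M, K, 2)

    m = len(individual_ids)
    dosages = np.full((m, k), MISSING, dtype=np.int8)
    for s in range(k):
        observed = alleles[:, s, :][alleles[:, s, :] != "0"]
        counts = Counter(observed.tolist())
        if len(counts) > 2:
            raise GenotypeFormatError(
                f"SNP {snp_ids[s]!r}: more than two alleles observed "
                f"({sorted(counts)})"
            )
        if not counts:
            continue  # SNP entirely missing
        # two most frequent symbols; frequency ties broken alphabetically
        pair = sorted(counts, key=lambda a: (-counts[a], a))[:2]
        ref = min(pair)
        both_obs = (alleles[:, s, :] != "0").all(axis=1)
        dosages[both_obs, s] = (alleles[both_obs, s, :] == ref).sum(axis=1)
    return GenotypeDataset(
        dosages=dosages,
        missing_mask=dosages == MISSING,
        individual_ids=individual_ids,
        populations=populations,
        snp_ids=snp_ids,
        chromosomes=chromosomes,
        positions=positions,
    )


def read_matrix(
    table,
    individual_ids: list[str] | None = None,
    populations: list[str] | None = None,
    snp_ids: list[str] | None = None,
    missing: int = MISSING,
) -> GenotypeDataset:
    """Build a dataset from a numeric matrix or a delimited text file.

    ``table`` may be an array-like of shape (M, K) with entries in {0, 1, 2},
    the missing sentinel, or NaN; or a path to a TSV/CSV file (see
    :func:`write_matrix` for the labelled layout). When ids are absent they
    are synthesized as ``ind_0 ... ind_{M-1}`` with empty population labels.
    """
    if isinstance(table, (str, Path)):
        return _read_matrix_file(Path(table), missing=missing)
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise GenotypeFormatError("matrix input must be 2-D")
    mask = np.isnan(arr) | (arr == missing)
    vals = np.where(mask, MISSING, arr)
    if not np.isin(vals[~mask], (0, 1, 2)).all():
        bad = vals[~mask][~np.isin(vals[~mask], (0, 1, 2))][0]
        raise GenotypeFormatError(
            f"matrix entry {bad!r} outside {{0,1,2}} and not the missing sentinel"
        )
    m, k = arr.shape
    return GenotypeDataset(
        dosages=vals.astype(np.int8),
        missing_mask=mask,
        individual_ids=list(individual_ids) if individual_ids else _default_ids(m),
        populations=list(populations) if populations else [""] * m,
        snp_ids=list(snp_ids) if snp_ids else [f"snp_{s}" for s in range(k)],
    )


def write_matrix(dataset: GenotypeDataset, path) -> Path:
    """Write a labelled TSV: individual_id, population, then one SNP column."""
    path = Path(path)
    codes = np.where(dataset.missing_mask, MISSING, dataset.dosages)
    df = pd.DataFrame(codes, columns=dataset.snp_ids)
    df.insert(0, "population", dataset.populations)
    df.insert(0, "individual_id", dataset.individual_ids)
    df.to_csv(path, sep="\t", index=False)
    return path


def _read_matrix_file(path: Path, missing: int) -> GenotypeDataset:
    with open(path) as fh:
        first = fh.readline()
    sep = "," if ("," in first and "\t" not in first) else "\t"
    if "individual_id" in first:
        df = pd.read_csv(path, sep=sep, dtype={"individual_id": str, "population": str})
        ids = df.pop("individual_id").tolist()
        pops = df.pop("population").fillna("").tolist() if "population" in df else None
        return read_matrix(
            df.to_numpy(dtype=float),
            individual_ids=ids,
            populations=pops,
            snp_ids=[str(c) for c in df.columns],
            missing=missing,
        )
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    return read_matrix(df.to_numpy(dtype=float), missing=missing)


def mean_impute(dataset: GenotypeDataset) -> np.ndarray:
    """Replace missing genotypes by the per-SNP mean of observed genotypes.

    Returns a float matrix; observed entries are unchanged. A SNP column with
    no observed genotypes is filled with 0 and reported via a warning (so
    bootstrap replicates never abort mid-run).
    """
    x = dataset.dosages.astype(float)
    mask = dataset.missing_mask
    if not mask.any():
        return x
    obs_counts = (~mask).sum(axis=0)
    sums = np.where(mask, 0.0, x).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        col_means = np.where(obs_counts > 0, sums / np.maximum(obs_counts, 1), 0.0)
    empty = np.flatnonzero(obs_counts == 0)
    if empty.size:
        warnings.warn(
            f"{empty.size} SNP column(s) entirely missing, filled with 0: "
            f"{[dataset.snp_ids[j] for j in empty[:10]]}",
            stacklevel=2,
        )
    x[mask] = np.broadcast_to(col_means, x.shape)[mask]
    return x


def _default_ids(m: int) -> list[str]:
    return [f"ind_{i}" for i in range(m)]


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n").rstrip("\r") for ln in fh if ln.strip()]
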