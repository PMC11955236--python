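"""PCA and metric-MDS embeddings of genotype data.

PCA operates on the Patterson-scaled dosage matrix: each SNP column is
centered and divided by sqrt(p(1-p)), the binomial standard deviation implied
by the estimated allele frequency p = mean/2. Designated individuals (e.g.
ancient samples with heavy missingness) can be projected onto an embedding
fitted on the remaining individuals by least squares against the SNP
loadings, using only their observed genotypes.

MDS reduces a pairwise distance matrix — Euclidean/Manhattan/Hamming between
individuals, or Hudson FST between populations — by SMACOF stress
majorization initialized from classical (Torgerson) scaling, so repeated runs
are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh, svd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from .io import GenotypeDataset, mean_impute


class ParameterError(ValueError):
    """Invalid analysis parameter (e.g. too many components)."""


@dataclass
class Embedding:
    """Low-dimensional coordinates of individuals or populations.

    ``coords`` is an R x D real matrix; row r is the projection of the
    individual (or population) named ``row_labels[r]``. ``explained_variance``
    holds the PCA eigenvalues (variances of the score columns) and
    ``explained_variance_ratio`` their share of the total variance.
    """

    coords: np.ndarray
    row_labels: list[str]
    level: str = "individual"
    populations: list[str] | None = None
    explained_variance: np.ndarray | None = None
    explained_variance_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ParameterError("coords must be 2-D")
        r, d = self.coords.shape
        if r < 2 or d < 1:
            raise ParameterError(f"need R >= 2 rows and D >= 1 columns, got {r} x {d}")
        self.row_labels = [str(x) for x in self.row_labels]
        if len(self.row_labels) != r:
            raise ParameterError("row_labels length does not match coords")
        if len(set(self.row_labels)) != r:
            raise ParameterError("row_labels must be unique")
        if self.populations is not None and len(self.populations) != r:
            raise ParameterError("populations length does not match coords")
        if self.explained_variance is not None:
            ev = np.asarray(self.explained_variance, dtype=float)
            if (np.diff(ev) > 1e-9 * max(ev.max(initial=0.0), 1.0)).any():
                raise ParameterError("explained_variance must be non-increasing")
            self.explained_variance = ev

    @property
    def n_rows(self) -> int:
        return self.coords.shape[0]

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords,
            columns=[f"dim_{j + 1}" for j in range(self.n_components)],
        )
        df.insert(0, "population", self.populations or [""] * self.n_rows)
        df.insert(0, "row_label", self.row_labels)
        return df

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative R x R distance matrix with zero diagonal."""

    values: np.ndarray
    row_labels: list[str]
    metric: str = ""
    level: str = "individual"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ParameterError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-10:
            raise ParameterError("distance matrix diagonal must be zero")
        if v.min(initial=0.0) < -1e-10:
            raise ParameterError("distances must be nonnegative")
        v = np.clip((v + v.T) / 2.0, 0.0, None)  # make symmetry exact
        np.fill_diagonal(v, 0.0)
        self.values = v
        self.row_labels = [str(x) for x in self.row_labels]
        if len(self.row_labels) != v.shape[0]:
            raise ParameterError("row_labels length does not match matrix")


def _patterson_scale(x: np.ndarray, mu: np.ndarray | None = None):
    """Center columns and divide by sqrt(p(1-p)) with p = mu/2.

    Columns whose implied frequency is fixed (p in {0,1}) carry no
    information and are mapped to all-zeros.
    """
    if mu is None:
        mu = x.mean(axis=0)
    p = mu / 2.0
    var = p * (1.0 - p)
    denom = np.sqrt(np.clip(var, 0.0, None))
    scaled = x - mu
    informative = denom > 1e-12
    scaled[:, informative] /= denom[informative]
    scaled[:, ~informative] = 0.0
    return scaled, mu, denom


def pca_embed(
    dataset: GenotypeDataset,
    n_components: int = 10,
    project_ids: list[str] | tuple[str, ...] = (),
) -> Embedding:
    """PCA of the Patterson-scaled genotype matrix.

    Individuals listed in ``project_ids`` are excluded from the fit and
    projected afterwards by least squares of their observed (Patterson-scaled
    with the fit-set statistics) genotypes against the SNP loadings — the
    behaviour of smartpca's ``lsqproject``. The sign of each component is
    fixed so that its largest-magnitude SNP loading is positive.
    """
    project_ids = list(project_ids)
    unknown = set(project_ids) - set(dataset.individual_ids)
    if unknown:
        raise ParameterError(f"unknown project_ids: {sorted(unknown)}")
    id_index = {iid: i for i, iid in enumerate(dataset.individual_ids)}
    proj_rows = np.array(sorted(id_index[i] for i in project_ids), dtype=int)
    fit_rows = np.setdiff1d(np.arange(dataset.n_individuals), proj_rows)
    m_fit, k = fit_rows.size, dataset.n_snps
    if m_fit < 2:
        raise ParameterError("fewer than 2 individuals remain to fit the PCA")
    if not 1 <= n_components <= min(m_fit - 1, k):
        raise ParameterError(
            f"n_components={n_components} must be in [1, min(M_fit-1, K)] "
            f"= [1, {min(m_fit - 1, k)}]"
        )

    fit_ds = GenotypeDataset(
        dosages=dataset.dosages[fit_rows],
        missing_mask=dataset.missing_mask[fit_rows],
        individual_ids=[dataset.individual_ids[i] for i in fit_rows],
        populations=[dataset.populations[i] for i in fit_rows],
        snp_ids=dataset.snp_ids,
    )
    xs, mu, denom = _patterson_scale(mean_impute(fit_ds))
    u, s, vt = svd(xs, full_matrices=False)
    comps = vt[:n_components]  # (D, K) loadings
    scores = u[:, :n_components] * s[:n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_components):
        i_max = int(np.argmax(np.abs(comps[j])))
        if comps[j, i_max] < 0:
            comps[j] = -comps[j]
            scores[:, j] = -scores[:, j]
    eigvals = s**2 / (m_fit - 1)
    explained = eigvals[:n_components]
    total = eigvals.sum()
    ratio = explained / total if total > 0 else np.zeros_like(explained)

    coords = np.empty((dataset.n_individuals, n_components))
    coords[fit_rows] = scores
    for i in proj_rows:
        obs = ~dataset.missing_mask[i] & (denom > 1e-12)
        if not obs.any():
            coords[i] = 0.0
            continue
        y = (dataset.dosages[i, obs].astype(float) - mu[obs]) / denom[obs]
        design = comps[:, obs].T  # (n_obs, D)
        coords[i], *_ = np.linalg.lstsq(design, y, rcond=None)
    return Embedding(
        coords=coords,
        row_labels=list(dataset.individual_ids),
        level="individual",
        populations=list(dataset.populations),
        explained_variance=explained,
        explained_variance_ratio=ratio,
    )


def hudson_fst(p1, n1, p2, n2) -> float:
    """Hudson ratio-of-averages FST between two populations.

    Arguments are per-SNP arrays: sample allele frequencies ``p`` in [0, 1]
    and haploid sample sizes ``n >= 2``. Returns sum(N_s)/sum(D_s) with
    N_s = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    D_s = p1(1-p2) + p2(1-p1), clamped to [0, 1]. With no polymorphism at
    all (every D_s = 0) the distance is defined as 0 with a warning.
    """
    p1, n1, p2, n2 = (np.atleast_1d(np.asarray(a, dtype=float)) for a in (p1, n1, p2, n2))
    if ((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)).any():
        raise ParameterError("allele frequencies must lie in [0, 1]")
    if ((n1 < 2) | (n2 < 2)).any():
        raise ParameterError("haploid sample sizes must be >= 2")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    den_sum = den.sum()
    if den_sum <= 0:
        warnings.warn("no polymorphism between populations; FST defined as 0", stacklevel=2)
        return 0.0
    return float(np.clip(num.sum() / den_sum, 0.0, 1.0))


def _population_frequencies(dataset: GenotypeDataset):
    """Per-population allele frequencies and haploid sample sizes per SNP."""
    pops = list(dict.fromkeys(p for p in dataset.populations if p))
    freqs, sizes = {}, {}
    dos = dataset.dosages.astype(float)
    for pop in pops:
        rows = [i for i, p in enumerate(dataset.populations) if p == pop]
        sub = dos[rows]
        obs = ~dataset.missing_mask[rows]
        counts = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop] = np.where(obs, sub, 0.0).sum(axis=0) / (2.0 * counts)
        sizes[pop] = 2.0 * counts
    return pops, freqs, sizes


def pairwise_distance(
    dataset: GenotypeDataset,
    metric: str = "euclidean",
    level: str = "individual",
) -> DistanceMatrix:
    """Pairwise distances between individuals or populations.

    Individual-level metrics are computed on the mean-imputed dosage matrix
    (Hamming counts unequal rounded dosages). The population level uses the
    Hudson FST aggregated over SNPs by default; the generic metrics are also
    accepted there and operate on per-population mean dosage vectors.
    """
    metric = metric.lower()
    level = level.lower()
    if metric == "fst":
        if level != "population":
            raise ParameterError("fst distance is defined at the population level only")
        pops, freqs, sizes = _population_frequencies(dataset)
        if len(pops) < 2:
            raise ParameterError("fst requires at least 2 populations with labels")
        r = len(pops)
        vals = np.zeros((r, r))
        for a in range(r):
            for b in range(a + 1, r):
                pa, pb = freqs[pops[a]], freqs[pops[b]]
                na, nb = sizes[pops[a]], sizes[pops[b]]
                ok = (na >= 2) & (nb >= 2) & np.isfinite(pa) & np.isfinite(pb)
                vals[a, b] = vals[b, a] = hudson_fst(pa[ok], na[ok], pb[ok], nb[ok])
        return DistanceMatrix(values=vals, row_labels=pops, metric="fst", level="population")
    if metric not in ("euclidean", "manhattan", "hamming"):
        raise ParameterError(f"unknown distance metric {metric!r}")

    x = mean_impute(dataset)
    if level == "population":
        pops = list(dict.fromkeys(p for p in dataset.populations if p))
        if len(pops) < 2:
            raise ParameterError("population level requires >= 2 labelled populations")
        x = np.stack(
            [
                x[[i for i, p in enumerate(dataset.populations) if p == pop]].mean(axis=0)
                for pop in pops
            ]
        )
        labels = pops
    elif level == "individual":
        labels = list(dataset.individual_ids)
    else:
        raise ParameterError(f"unknown level {level!r}")
    if metric == "euclidean":
        d = squareform(pdist(x, "euclidean"))
    elif metric == "manhattan":
        d = squareform(pdist(x, "cityblock"))
    else:  # hamming on rounded dosages, as a count of differing SNPs
        d = squareform(pdist(np.rint(x), "hamming")) * x.shape[1]
    return DistanceMatrix(values=d, row_labels=labels, metric=metric, level=level)


def classical_scaling(d: np.ndarray, n_components: int) -> np.ndarray:
    """Torgerson classical scaling of a distance matrix (MDS init)."""
    r = d.shape[0]
    j = np.eye(r) - np.ones((r, r)) / r
    b = -0.5 * j @ (d**2) @ j
    w, v = eigh(b)
    order = np.argsort(w)[::-1][:n_components]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def _raw_stress(d: np.ndarray, coords: np.ndarray) -> float:
    emb = squareform(pdist(coords))
    iu = np.triu_indices_from(d, k=1)
    return float(((d[iu] - emb[iu]) ** 2).sum())


def mds_embed(
    distance: DistanceMatrix,
    n_components: int = 2,
    seed: int = 0,
) -> Embedding:
    """Metric MDS by SMACOF stress majorization.

    Initialized deterministically from classical (Torgerson) scaling, so the
    result depends only on the distance matrix. The final stress never
    exceeds the stress of the initialization (majorization is monotone).
    """
    d = distance.values
    r = d.shape[0]
    if not 1 <= n_components <= r - 1:
        raise ParameterError(f"n_components must be in [1, R-1] = [1, {r - 1}]")
    if np.allclose(d, 0.0):
        coords = np.zeros((r, n_components))
    else:
        init = classical_scaling(d, n_components)
        coords, _stress = smacof(
            d,
            metric=True,
            n_components=n_components,
            init=init,
            n_init=1,
            max_iter=1000,
            eps=1e-12,
            random_state=seed,
            normalized_stress=False,
        )
    return Embedding(
        coords=coords,
        row_labels=list(distance.row_labels),
        level=distance.level,
    )
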