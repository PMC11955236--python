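# genostab

Bootstrap-based stability estimation for PCA and MDS embeddings of SNP
genotype data.

PCA and MDS scatter plots are a staple of population genetics, but a single
embedding gives no hint of how reproducible it is: resampling the SNPs can
move individuals, merge clusters, or flip whole axes. `genostab` quantifies
that uncertainty for a genotype matrix of M individuals × K biallelic SNPs
(dosages 0/1/2 plus a missing code) by drawing N bootstrap replicates of the
K SNP columns *with replacement*, re-embedding each replicate, and comparing
the replicate embeddings:

- **PS (overall stability).** Each pair of replicate embeddings P_u, P_v is
  standardized (centered, trace(PPᵀ)=1) and aligned by Procrustes analysis;
  the minimal squared Frobenius residual is the disparity D_{u,v} ∈ [0,1] and
  the pairwise similarity is 1 − D_{u,v}. PS is the mean similarity over all
  N(N−1)/2 pairs; 1 means every replicate projects all individuals
  identically.
- **PCS (cluster stability).** For each matched pair, both embeddings are
  clustered independently with k-means (the same k, chosen by a BIC grid
  search between 3 and the number of populations or √M when k is not given)
  and compared with the Fowlkes–Mallows index; PCS is the mean over pairs.
- **PSV (per-individual support).** After aligning all replicates to a
  common frame, PSV_i = 1 − Gini dispersion of individual i's projections:
  1 − Σ_{u<v}‖x_i^u − x_i^v‖ / (N·Σ_u‖x_i^u‖). Low-PSV individuals are the
  ones whose placement should not be over-interpreted — typical for
  sparsely observed ancient samples projected onto a modern reference PCA.

PCA is computed natively on the Patterson-scaled dosage matrix (per-SNP
centering and division by √(p̂(1−p̂))), with least-squares projection of
designated individuals onto an embedding fitted without them. MDS is SMACOF
stress majorization of Euclidean/Manhattan/Hamming distances between
individuals or Hudson FST distances between populations. A heuristic
convergence check (subset-PS spread) can stop the bootstrap early.

Also included: readers/writers for EIGENSTRAT text triplets, PLINK text
pedigree pairs and generic numeric matrices; a Balding–Nichols generator of
structured synthetic genotypes with missing-data and noise distortion
protocols.

## Worked example

```python
from genostab import SimulationConfig, run_analysis, simulate_genotypes

dataset = simulate_genotypes(
    SimulationConfig(n_populations=2, n_per_population=30, n_snps=2000,
                     divergence_fst=0.15, seed=7)
)
report = run_analysis(dataset, analysis="pca", n_components=5, n_max=20, seed=7)
print(f"PS={report.ps:.3f} PCS={report.pcs:.3f} k={report.k} "
      f"n={report.n_replicates} converged={report.converged}")
```

prints

```
PS=0.624 PCS=0.762 k=3 n=12 converged=True
```

Two populations at divergence F=0.15 with only 2000 SNPs give a moderately
stable embedding: resampling the SNPs preserves the overall configuration
imperfectly (PS 0.62) and the k-means clusters somewhat more reliably
(PCS 0.76); the convergence heuristic stopped after 12 of the allowed 20
replicates. `report.psv.values` holds the per-individual support values.

The scripts in `examples/` walk through each capability (full stability
analysis, Procrustes comparison, population-level FST + MDS, projection of
sparsely observed individuals); each prints its numbers with a line on what
they mean.

There is also a thin CLI:

```sh
genostab simulate --n-populations 2 --n-snps 5000 --fst 0.2 --seed 7 --prefix sim
genostab run --input sim --format eigenstrat --analysis pca --seed 7 --outdir out/
```

which writes `out/report.json` (PS, PCS, k, replicate count, convergence
flag) and `out/psv.tsv` (support values, least stable first).

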