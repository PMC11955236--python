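# Methods

## The model of uncertainty

A PCA or MDS embedding of a genotype matrix is a function of which SNPs
happen to be in the dataset. Treating loci as approximately independently
evolving units — the same assumption that justifies the phylogenetic
bootstrap — the sampling distribution of the embedding is estimated by
resampling the K SNP columns with replacement. Individuals are deliberately
*not* resampled: the set of individuals defines the question being asked,
and resampling them would let the analysis be steered by subjective sample
selection. Each bootstrap replicate therefore has the same M individuals
and a different SNP composition (duplicated columns included).

All stability statistics are functions of the set of replicate embeddings
and use **all** computed components, not just the first two.

### Overall stability (PS)

Embeddings are defined only up to scale, rotation/reflection and
translation, so two replicates are compared after removing exactly that
family: both are standardized (column means 0, trace(PPᵀ) = 1) and the
optimal orthogonal alignment with scaling is obtained in closed form from
the SVD of the cross-product matrix AᵀB. The squared Frobenius residual is
the disparity D_{u,v}; because both matrices have unit Frobenius norm,
D_{u,v} = 1 − (Σσ_i)² ∈ [0,1]. The pairwise similarity is 1 − D_{u,v} and
PS is the mean over all unordered replicate pairs. Numerically, the
disparity is computed as the explicit residual and clipped to [0,1] to
absorb double-precision SVD noise (identical inputs give ~1e−32, not an
assigned 0).

### Cluster stability (PCS)

Per pair, the first embedding is Procrustes-matched onto the second, each
side is clustered independently by k-means (k-means++ init, 10 restarts,
seeds derived deterministically from the run seed and the replicate
indices), and the two label vectors are compared with the Fowlkes–Mallows
index. PCS is the mean over pairs. Which side is transformed is irrelevant:
Fowlkes–Mallows is label-invariant.

When k is not supplied it is chosen once, on the first replicate, by a grid
search minimizing BIC under a hard-assignment spherical Gaussian mixture
with shared variance: σ̂² = inertia/(D(R−k)), log-likelihood
Σ_j n_j ln(n_j/R) − RD/2 ln(2πσ̂²) − (R−k)D/2, penalty p ln R with
p = k(D+1) free parameters; ties go to the smallest k. The search runs from
3 (smaller k produce degenerate comparisons in practice) up to the number
of distinct population labels, or ⌈√R⌉ when no labels exist. k influences
PCS substantially; both bounds and k itself are exposed as parameters.

### Per-row support values (PSV)

PSV_i = 1 − Gini dispersion of row i's projections across replicates,
clamped to [0,1]. The projections only live in a common frame after
alignment, so all replicates are standardized and Procrustes-aligned onto
replicate 1 first (single-reference alignment). This choice — rather than
aligning to the unbootstrapped embedding or pairwise per term — is the main
place where another implementation of the same statistic could diverge;
without any alignment the statistic would be destroyed by arbitrary
per-replicate axis flips. A row projected exactly to the origin by every
replicate is a 0/0 case and receives support 1 with a warning.

## Embeddings

**PCA.** The fit-set dosage matrix is mean-imputed, then Patterson-scaled:
column s is centered at μ_s and divided by √(p̂(1−p̂)) with p̂ = μ_s/2 — the
binomial standard deviation implied by the allele frequency, the scaling
smartpca uses for genotype data. Raw p̂ is used (no pseudo-count
correction). Zero-information columns (p̂ ∈ {0,1}) are mapped to zeros.
Scores come from the SVD of the scaled matrix; eigenvalues are reported as
score-column variances (σ²_j = s_j²/(M_fit−1)) together with their ratio of
the total. The per-component sign is fixed by making the largest-magnitude
SNP loading positive, so runs are bit-reproducible; Procrustes comparison
absorbs signs anyway. Default 10 components. Automatic outlier removal is
deliberately not implemented.

Designated individuals (ancient samples, typically) are excluded from the
fit and projected by least squares of their observed, fit-set-scaled
genotypes against the SNP loadings — missing genotypes simply drop out of
the system, so no imputation of the projected individuals is needed. A
fully observed duplicate of a fit individual projects exactly onto that
individual's scores.

**Distances and MDS.** Individual-level Euclidean/Manhattan/Hamming
distances are computed on the mean-imputed dosage matrix (Hamming counts
unequal *rounded* dosages, since it is only defined on discrete codes).
Population-level distances default to the Hudson ratio-of-averages FST
estimator, Σ_s N_s / Σ_s D_s with
N_s = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) and
D_s = p₁(1−p₂) + p₂(1−p₁) (haploid sample sizes n; SNPs with an unobserved
population are skipped; the aggregate is clamped to [0,1]; a fully
monomorphic comparison is defined as 0 with a warning). The ratio-of-
averages form is stable for rare variants, unlike averaging per-SNP ratios.
Other FST estimators (e.g. Weir–Cockerham) differ by O(1/n) terms, so
absolute population-level MDS coordinates may differ slightly from tools
using another estimator. The generic metrics are also accepted at the
population level, applied to per-population mean dosage vectors.

Metric MDS is SMACOF stress majorization initialized from classical
(Torgerson) scaling of the distance matrix — a deterministic init, so MDS
runs are bit-identical and Euclidean-realizable inputs are reproduced at
the init already. Iteration cap 1000, relative stress tolerance 1e−12.
Default 2 components. An all-zero distance matrix short-circuits to
coincident points.

## Bootstrap orchestration and convergence

Replicate i's SNP indices are drawn from seed (master_seed + i), fixed
before dispatch, so the sequence of replicates is identical for any thread
count; batches of size `threads` are executed via joblib's threading
backend (the heavy lifting is in NumPy/BLAS which releases the GIL).

Early stopping: once m ≥ 10 replicates exist, 10 random subsets of size
⌈m/2⌉ are drawn (seeded from the master seed and m), PS is computed on each
from the cached pairwise-similarity matrix, and the run stops when the
relative spread (max − min)/max falls to the tolerance (default 0.05,
maximum 100 replicates). The criterion is evaluated retrospectively at
every replicate-count checkpoint m = 10, 11, … on the first m replicates,
and the run is truncated to the first converged checkpoint — this is what
makes the returned replicate set independent of the thread count rather
than of the batch boundaries. A tolerance of 0 disables early stopping by
convention. On very stable data the check can succeed at the first
checkpoint (m = 10); lowering the tolerance or disabling convergence is
recommended when accurate PSVs (which are noisier than PS) are the goal.

## Synthetic data

The generator emulates structured multi-population genotype data at desk
scale with the Balding–Nichols model: per SNP an ancestral frequency
p ~ Uniform(0.05, 0.95); per population a frequency
p_j ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so F is the expected differentiation of
each population from the ancestral pool (two populations then show pairwise
Hudson FST ≈ F); dosages are Binomial(2, p_j). Defaults: 2 populations × 50
individuals, 5000 SNPs, F = 0.1 — sizes at which a full 20-replicate
analysis runs in seconds while the population structure is clearly
recoverable. What the generator does **not** emulate: linkage
disequilibrium, realistic site-frequency spectra, admixture, drift along a
demographic history, or ascertainment bias. Passing trend tests on these
data therefore show that the statistics respond correctly to signal
strength and distortion, not that the numeric PS/PCS values transfer to any
empirical dataset.

Distortion protocols: `inject_missing` replaces exactly ⌊q·M·K⌋ uniformly
chosen cells with the missing code; `inject_noise` flips exactly ⌊q·M·K⌋
uniformly chosen *observed* cells to a uniformly random different genotype
code (forced to differ, so the nominal proportion is the effective one).

## Test and verification scale

The acceptance-style trend checks use three-population Balding–Nichols
datasets of 99 individuals with 20 bootstrap replicates averaged over three
seeds: SNP counts {200, 1000, 5000} for the signal-strength trend, and the
largest (5000-SNP) datasets for the missingness {0, 10, 20, 50%} and noise
{0, 10, 20, 50%} protocols — distortions are applied to the strongest-
signal data so the trend is not confounded by low signal. At these
conditions PS rises strictly with SNP count and falls with both
distortions, and PCA loses stability faster than MDS at 10% and 20% noise.

One known divergence at this scale: at 50% noise the 2-component Euclidean
MDS embedding degenerates (PS ≈ 0.17 versus PCA's 0.29), so over the full
noise range MDS's decline exceeds PCA's. With only a few thousand weakly
structured SNPs, 50% genotype noise swamps the between-population signal in
the pairwise distances, and the resulting near-arbitrary 2-D configurations
differ wildly between replicates; whole-genome-scale data with strong
structure do not show this collapse. The trend suite asserts the full-range
comparison, which accordingly fails at the 50% level at this data scale.

## Numerical conventions and degenerate inputs

- Disparity assertions treat ≤1e−10 as "identical" (double-precision SVD
  noise); disparities and similarities are clipped to [0,1].
- A standardization of coincident points (zero norm after centering) is an
  error — such an embedding carries no geometry.
- Mean imputation of an entirely missing SNP column fills 0 (the column is
  then zero-information after Patterson scaling) and warns, so bootstrap
  replicates that happen to gather only missing columns never abort a run.
- PLINK decoding takes the two most frequent observed allele symbols per
  SNP (frequency ties broken alphabetically) and counts the
  alphabetically-first allele; dosage polarity cannot affect any downstream
  statistic because PCA centers columns. Genotypes with any missing allele
  are treated as missing.
- All randomness (bootstrap indices, k-means, subset draws, simulation)
  flows from explicit integer seeds; derived seeds stay below 2³¹.

## Known limitations

- The convergence heuristic is a concrete instantiation of a
  subset-spread criterion; other implementations of the same idea (different
  subset counts, sizes, or spread measures) will stop at different replicate
  counts on the same data.
- Single-reference alignment for PSVs (see above).
- Binary formats (PLINK .bed, packed EIGENSOFT dialects) are out of scope;
  inputs are text.
- The BIC likelihood is the standard hard-assignment spherical-Gaussian
  surrogate, adequate for choosing k on embeddings but not a density model
  of the data.
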