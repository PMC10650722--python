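# Methods

This note documents the models and procedures implemented in `epitof`,
the parameters that matter, the synthetic-data generator's assumptions,
and the numerical and design choices that were genuinely open.

## Residual normalization

Mass-cytometry HPTM measurements confound the abundance of a specific
mark with the cell's total histone content (cell size, cycle stage,
staining efficiency). The package removes this confound in two steps.

1. **Abundance transform.** Every channel (HPTM and total-histone alike,
   for symmetry) is divided by a cofactor, default 50, chosen to bring
   ion counts onto an O(1) scale. A compressive `arcsinh(x/50)` variant
   is available through `TransformSpec` for data with extreme outliers;
   the transform used is recorded with the fit so results are
   reproducible either way.
2. **Per-sample residual regression.** For each sample independently and
   each HPTM *j*, ordinary least squares of the transformed mark on an
   intercept plus transformed total H3 and H4. The residual ε\_ij is the
   normalized abundance. Fitting per sample (never pooled) means
   sample-specific staining efficiency is absorbed by the per-sample
   coefficients; it also means a sample needs at least 3 cells to
   identify the three parameters (fewer is an error).

Exact identities that follow from OLS — residuals sum to zero per
sample and are orthogonal to the transformed regressors, and
re-regressing residuals changes nothing — are asserted in the test
suite at `1e-8` relative tolerance against a normal-equations oracle.

*Degenerate designs.* If H3/H4 are constant or collinear within a
sample, the collinear column is dropped (greedy left-to-right rank
selection, so the intercept always survives) and the fit degrades to
mean-centering in the fully degenerate case; the per-(sample, HPTM) fit
table carries a `rank_ok` flag and a warning is logged.

The total-histone channels are regressors only; they are excluded from
all downstream features, since their linear effect has by construction
been removed.

## Embedding and graph clustering

Cells are subsampled uniformly without replacement within strata
(default stratum = disease group, default 10,000 cells per stratum,
matching a 40,000-cell analysis over two antibody panels × two groups),
then embedded in 2-D with UMAP, `n_neighbors=15`, `min_dist=0.1`, fixed
seed. Clustering is PhenoGraph-style **on the embedded coordinates**:
exact Euclidean kNN graph, edges reweighted by the Jaccard overlap of
the endpoints' k-neighbor sets, and modularity-maximizing community
detection. For the community step we use the Leiden algorithm with the
modularity objective and an explicit seed: it optimizes the same
objective as classic Louvain but is deterministic under a seed and does
not produce badly-connected communities. Labels are renumbered so
cluster 1 is the largest, with ties broken by original community id.

**Choosing k.** The neighborhood size k sets the resolution: modularity
optimization on a kNN graph splits a uniform cloud of m points into
patches unless k is of the order of m. Empirically, planted
well-separated subpopulations are recovered exactly when k ≳ 0.6× the
smallest subpopulation, and oversplit when k is much smaller. The
default k=1000 on a 40,000-cell embedding sits at this cluster-size
scale for clusters of a few thousand cells; scaled-down analyses in the
tests keep the same ratio (e.g., k=1000 on 4,000 cells for ~1,300-cell
clusters). k must be below the number of cells.

*Numerics.* Shared-neighbor counts are computed as a sparse
boolean-matrix product restricted to kNN edges, which costs O(n·k²);
when k exceeds 5% of n (and n ≤ 6,000) a dense BLAS product is cheaper
and is used instead. Counts are exact in float32 (bounded by k ≤ 2²⁴).
A dataset in which all points coincide has no neighborhood structure
and is returned as a single cluster.

## Cluster statistics

**Composition and enrichment.** Per-sample cluster proportions (rows sum
to 1; absent pairs are 0) are compared between groups per cluster with
a two-sided Wilcoxon rank-sum test and BH correction across clusters. A
cluster's direction (disease- vs healthy-enriched) is the sign of the
median-proportion difference and is reported only when q < α
(default 0.05).

**Exact rank-sum.** In `auto` mode the test is exact when both groups
have ≤ 10 observations and no value is shared across groups, otherwise
a normal approximation with tie and continuity corrections. The exact
p-value is computed from the full permutation distribution of the
midrank sum via a subset-sum dynamic program (midranks are halves, so
doubling makes them integers); this handles within-group ties exactly
and matches exhaustive enumeration for every case with ≤ 8 per group in
the tests. Two-sided p is `min(1, 2·min(P≤, P≥))`.

An important consequence at study scale: with 5 samples per group the
smallest attainable exact two-sided p is 2/252 ≈ 0.0079 (exposed as
`MIN_P_5V5`); composition comparisons cannot be more significant than
this floor, whatever the effect.

**Cluster-defining marks.** For each (cluster, HPTM) pair, in-cluster
cells versus all other cells: Cohen's D with the pooled SD, rank-sum p,
BH across all pairs (`family="global"`, default) or within each cluster
(`family="per_cluster"` — both offered because the choice of family is
a genuinely open convention). Singleton clusters are skipped with a
warning. D is undefined (NaN) when the pooled SD is zero.

**Heatmap matrix.** Median residual per (cluster, HPTM); rows and
columns ordered by average-linkage hierarchical clustering with
Euclidean distance; a per-cluster annotation gives the fold change of
disease vs healthy mean composition, colored magenta
(disease-abundant), green (healthy-abundant) or gray (ns) from the
enrichment direction. Group *means* are used for this fold change
(medians would also be defensible; the statistic is a parameter).

**Why BH.** "FDR-adjusted" is read as Benjamini–Hochberg, the standard
procedure; it is applied within each test family.

## Differential accessibility

Counts are normalized by median-of-ratios size factors (regions
containing any zero are excluded from the geometric-mean reference;
CPM is available for parity checks), log2(x+1)-transformed, and tested
per region with a Welch t-test (variance equality is never assumed).
log2 fold change is the difference of group means on the log scale. A
region is called only by the joint filter `q < α` and
`|linear FC| ≥ min_fc` (default 2, applied in both directions). Regions
with identical values in both groups have an undefined t statistic and
are assigned p = 1 (no evidence). The proprietary multi-model testing
used by some commercial pipelines is deliberately replaced by this
transparent Welch-on-log-counts test; a negative-binomial test is a
noted extension point.

TSS enrichment aggregates fragment coverage over ±5,000 bp windows
around TSSs (10,001 positions, strand-flipped for minus-strand TSSs);
the score is the mean coverage of the central 100 bp over the mean of
the two outer 100-bp flanks — ~1 for uniform background. The score's
sampling noise scales like sqrt(G/(N·W)) for N fragments on a G-bp
background and W-bp windows, which sets the fragment counts used in the
tests.

## Synthetic-data generator

The generator emulates exactly the structure the pipeline assumes:

- latent per-cell total-histone levels (H3, H4) are correlated
  lognormals (log-scale SDs 0.4/0.35, correlation 0.7) — heavy-tailed,
  strictly positive;
- each HPTM, in transformed units, is
  `baseline + b1·H3 + b2·H4 + subpop shift + N(0, noise_scale)`, with
  default coupling (0.8, 0.4) and noise SD 0.3, then clipped at zero
  and mapped back to raw scale by the cofactor; measured H3/H4 carry 2%
  lognormal assay noise;
- per-sample lognormal-free marker offsets of SD 0.05 model biological
  sample-to-sample variation;
- subpopulations are drawn i.i.d. per cell from group-specific mixing
  weights, so disease enrichment of a subpopulation is a planted,
  recoverable signal;
- defaults mirror the study design: 5 samples per group and an
  11-mark methylation-style panel regressed on H3/H4.

`planted_study_config` builds the scaled-down recovery design used in
testing: 4 samples/group × 2,000 cells, each non-baseline subpopulation
shifting a rolling triplet of marks by 2.0 transformed units (~6.7
noise SDs, comfortably above the ≥5-SD regime where recovery is
expected), equal pooled subpopulation sizes, and disease enrichment
alternating across subpopulations with a 3:1 ratio. The alternation
matters: group mixing weights are compositional, so enriching one
subpopulation necessarily depletes others, and spreading the signal
keeps the BH-adjusted q of the enriched cluster below 0.05 despite the
4-vs-4 exact-test floor of 2/70 ≈ 0.0286.

The region simulator draws negative-binomial counts
(`var = μ + dispersion·μ²`, lognormal region means, ±10% lognormal
library sizes) and scales the disease-group mean of a planted fraction
of regions by `2^log2fc`.

**What the generator does not model** (hence what passing tests do not
show about real data): instrument artifacts (bead normalization drift,
doublets, isotopic spillover, dead cells), nonlinear or saturating
histone coupling, per-cell-type panel correlations beyond the planted
shifts, batch structure beyond per-sample offsets, and genomic
covariates of accessibility (GC, mappability, peak width). Real-data
cluster structure is far less separated than the planted designs.

## Calibration study

The null-calibration study (zero planted effects) checks that the
enrichment and signature tests reject at their nominal level. Two
design choices: (i) it uses 10 samples per group, because with 5+5 the
exact rank-sum distribution is so discrete that the attainable level
nearest 0.05 is 8/252 ≈ 0.032 and no test can sit at the nominal level;
with 10+10 the null distribution is fine-grained near α. (ii) Any cell
partition that is independent of the group label is a valid null
clustering, so the replicates use the simulator's ground-truth
subpopulation labels as the cluster assignment rather than re-running
the embedding 200 times. Composition p-values at 10v10 usually fall to
the tie-corrected normal approximation (proportions share denominators,
so cross-group ties are common), which is slightly conservative — the
observed rejection rate sits a little below 0.05, within the binomial
99% band.

## Determinism

All randomness flows through explicit integer seeds;
per-stage sub-seeds are derived with `numpy.random.SeedSequence`. UMAP
with a fixed `random_state` runs single-threaded and is reproducible on
a given platform; Leiden takes an explicit seed; subsampling uses a
seeded generator. A full pipeline rerun with the same config and seed
produces byte-identical tabular outputs (verified by sha256 digests in
the run manifest).

## Problem sizes used in testing

Desk-scale sizes were chosen so the full suite runs in a few minutes on
one CPU: planted-recovery studies simulate 16,000 cells and analyze a
4,000-cell stratified subsample; the null calibration runs 200
replicates of 3,000 cells; the accessibility studies use 400–1,000
regions with up to 20 samples per group. The study-scale defaults
(10,000 cells per stratum, k=1000) remain the package defaults.

## Known limitations

- Clustering operates on the 2-D UMAP embedding (a faithful-but-
  debatable choice, kept because the method being reproduced specifies
  it); marker-space clustering would avoid embedding distortions.
- The composition test treats samples as exchangeable units and ignores
  cell counts; a count-aware (e.g., binomial mixed) model is out of
  scope.
- Welch-on-log-counts is a pragmatic substitute for count-likelihood
  differential testing and will lose power at very low counts.
- The exact rank-sum enumeration is O(n·Σranks) per test and intended
  for the small per-group sizes where it is used.
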