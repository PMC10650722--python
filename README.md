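# epitof

Single-cell histone post-translational-modification (HPTM) profiling for
mass-cytometry (EpiTOF) data, with a companion differential
chromatin-accessibility stage for ATAC-style region-count matrices.

The package is aimed at the comparison of a disease cohort against
healthy controls at the level of single-cell epigenetic state — the
motivating setting is CD34+ hematopoietic stem and progenitor cells from
juvenile myelomonocytic leukemia (JMML) spleens ("JSP") versus healthy
umbilical cord blood ("HCB"/"UCB") — but every stage is generic over the
marker panel and group labels.

## What it computes

**Normalization.** Raw per-cell ion-count abundances are rescaled,
`x_transformed = x_raw / 50` (an `arcsinh(x/50)` variant is available),
and each HPTM *j* is then regressed, per sample, on the transformed
total-histone channels:

    HPTM_ij = β0 + β1·H3_i + β2·H4_i + ε_ij

The OLS residual ε\_ij is the normalized abundance of mark *j* in cell
*i*; this removes per-cell differences in total histone content before
any comparison.

**Embedding and clustering.** A stratified subsample (default 10,000
cells per stratum) is embedded with UMAP (`n_neighbors=15`,
`min_dist=0.1`) and clustered PhenoGraph-style on the 2-D embedding:
exact k-nearest-neighbor graph (default `k=1000`), edges weighted by the
Jaccard overlap of neighbor sets, communities by seeded
modularity-maximizing (Leiden) detection. Cluster 1 is always the
largest.

**Cluster statistics.** Per-sample cluster composition; per-cluster
disease-vs-healthy comparison by two-sided Wilcoxon rank-sum (exact
permutation enumeration for small groups, normal approximation with tie
and continuity corrections otherwise) with Benjamini–Hochberg FDR across
clusters; cluster-defining marks by Cohen's D plus rank-sum FDR of
in-cluster versus all other cells; a cluster × HPTM median-residual
matrix with average-linkage dendrogram orders for heatmap display. Note
that with 5 samples per group the exact two-sided rank-sum p-value can
never fall below 2/252 ≈ 0.0079.

**Differential accessibility.** Region × sample counts are
library-normalized (median-of-ratios by default, CPM optional), tested
per region with a Welch t-test on `log2(normalized + 1)`, BH-adjusted,
and called up/down only when `q < 0.05` **and** `|fold change| ≥ 2`.
A ±5,000 bp TSS-enrichment profile is included as library QC.

**Synthetic data.** `epitof.simulate` generates EpiTOF-like cell
matrices (heavy-tailed abundances linearly coupled to latent H3/H4,
planted subpopulations with shifted marks and group-specific mixing) and
negative-binomial region counts with planted differential regions, so
the whole pipeline is testable with known ground truth.

## Worked example

```python
from epitof import EpiTofModel, SubsampleSpec, simulate_epitof
from epitof.simulate import planted_study_config

config = planted_study_config(n_subpops=3, n_samples_per_group=4,
                              cells_per_sample=2000, seed=11)
cells, truth = simulate_epitof(config)
model = EpiTofModel(cells, subsample=SubsampleSpec(target=2000), k=1000)
results = model.fit(seed=5)
print(results.summary())
```

```
EpiTOF profiling summary
========================
cells analyzed: 4000 (of 16000; seed 5)
clusters: 3 (graph k=1000, modularity 0.667)
differentially composed clusters (q < 0.05): 2
  cluster 2: HCB-enriched (median JSP 0.172 vs HCB 0.500, q=4.29e-02)
  cluster 3: JSP-enriched (median JSP 0.488 vs HCB 0.170, q=4.29e-02)
significant cluster-defining marks: 20
  cluster 1 / H3K9me2: d=+6.66, q=0.00e+00
  cluster 1 / H3K4me2: d=+6.53, q=0.00e+00
  ...
```

The three planted subpopulations come back as exactly three clusters;
the disease-enriched subpopulation's cluster is flagged JSP-enriched at
q < 0.05, and its planted mark shifts appear as the cluster-defining
HPTMs with the planted signs. `results.plot_embedding()` and
`results.plot_heatmap()` draw the corresponding figures, and
`results.enrichment` / `results.signatures` are plain DataFrames.

The accessibility stage works the same way:

```python
from epitof import DifferentialAccessibility, simulate_region_counts

matrix, truth = simulate_region_counts(n_regions=1000, n_per_group=20,
                                       frac_diff=0.1, log2fc=3.0,
                                       dispersion=0.05, seed=42)
atac = DifferentialAccessibility(matrix, alpha=0.05, min_fc=2.0).fit()
print(atac.summary())
```

```
Differential accessibility (Welch t on log2 normalized counts)
  regions: 1000   normalization: median_of_ratios
  filter: q < 0.05 and |FC| >= 2
  up in JMML: 100   down in JMML: 0
```

All 100 planted regions are recovered with no false calls.

A command-line interface mirrors the library
(`epitof simulate|normalize|cluster|stats|atac-diff|run|io`), and
`epitof run --config run.yaml` executes the whole pipeline with one
config file, writing every stage table plus a `manifest.json` with
sha256 digests for exact reproduction.

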