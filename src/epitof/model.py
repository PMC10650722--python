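"""End-to-end single-cell HPTM profiling model.

``EpiTofModel`` composes the pipeline stages — residual normalization,
stratified subsampling, UMAP embedding, Jaccard-kNN community clustering,
composition/enrichment statistics and mark signatures — behind a
statsmodels-style ``fit()`` that returns an ``EpiTofResults`` object.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment, cluster_phenograph
from .cluster_stats import (CompositionTable, cluster_defining_marks,
                            cluster_enrichment, composition_table,
                            heatmap_matrix)
from .containers import CellMatrix, NormalizedMatrix
from .embedding import Embedding, SubsampleSpec, embed_umap, stratified_subsample
from .normalize import (ResidualRegression, TransformSpec, ValidationError)


def _stage_seeds(seed: int, n: int = 3) -> list[int]:
    """Deterministic per-stage sub-seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


class EpiTofModel:
    """Single-cell HPTM profiling of disease vs healthy samples.

    Parameters
    ----------
    cells : CellMatrix
        Raw per-cell marker abundances with sample/group annotation.
    transform : TransformSpec
        Abundance transform applied before the residual regression
        (default: divide by 50).
    subsample : SubsampleSpec
        Per-stratum subsampling design (default 10,000 cells per disease
        group; the study embeds 40,000 cells over two panels x two groups).
    n_neighbors, min_dist : UMAP parameters (study values 15 and 0.1).
    k : neighborhood size of the clustering graph (study value 1000 on
        40,000 cells; scale down with dataset size).
    alpha : FDR threshold for enrichment and signature calls.
    signature_family : BH family for mark signatures, ``global`` (all
        cluster x HPTM pairs) or ``per_cluster``.
    """

    def __init__(self, cells: CellMatrix,
                 transform: TransformSpec = TransformSpec(),
                 subsample: SubsampleSpec = SubsampleSpec(),
                 n_neighbors: int = 15, min_dist: float = 0.1,
                 k: int = 1000, alpha: float = 0.05,
                 signature_family: str = "global"):
        if not 0 < alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        self.cells = cells
        self.transform = transform
        self.subsample = subsample
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.k = k
        self.alpha = alpha
        self.signature_family = signature_family

    def fit(self, seed: int = 0) -> "EpiTofResults":
        s_sub, s_umap, s_cluster = _stage_seeds(seed)
        norm_res = ResidualRegression(self.cells, transform=self.transform).fit()
        spec = replace(self.subsample, seed=s_sub)
        subset, positions = stratified_subsample(norm_res.normalized, spec)
        embedding = embed_umap(subset, n_neighbors=self.n_neighbors,
                               min_dist=self.min_dist, seed=s_umap)
        assignment = cluster_phenograph(embedding, k=self.k, seed=s_cluster)
        sample_groups = pd.crosstab(subset.sample_id, subset.group).idxmax(axis=1)
        composition = composition_table(assignment, subset.sample_id, sample_groups)
        enrichment = cluster_enrichment(composition, alpha=self.alpha)
        signatures = cluster_defining_marks(subset, assignment, alpha=self.alpha,
                                            family=self.signature_family)
        heatmap = heatmap_matrix(subset, assignment, enrichment)
        return EpiTofResults(self, seed, norm_res, subset, positions,
                             embedding, assignment, composition, enrichment,
                             signatures, heatmap)


class EpiTofResults:
    """Fitted pipeline state: normalization through cluster statistics."""

    def __init__(self, model: EpiTofModel, seed: int, normalization,
                 subset: NormalizedMatrix, positions: np.ndarray,
                 embedding: Embedding, clusters: ClusterAssignment,
                 composition: CompositionTable, enrichment: pd.DataFrame,
                 signatures: pd.DataFrame, heatmap):
        self.model = model
        self.seed = seed
        self.normalization = normalization
        self.subset = subset
        self.positions = positions
        self.embedding = embedding
        self.clusters = clusters
        self.composition = composition
        self.enrichment = enrichment
        self.signatures = signatures
        self.heatmap = heatmap

    @property
    def n_clusters(self) -> int:
        return self.clusters.n_clusters

    def summary(self) -> str:
        enriched = self.enrichment[self.enrichment["direction"] != "ns"]
        sig = self.signatures[self.signatures["significant"]]
        lines = [
            "EpiTOF profiling summary",
            "========================",
            f"cells analyzed: {self.subset.n_cells} "
            f"(of {self.model.cells.n_cells}; seed {self.seed})",
            f"clusters: {self.n_clusters} "
            f"(graph k={self.clusters.k_neighbors}, "
            f"modularity {self.clusters.modularity:.3f})",
            f"differentially composed clusters (q < {self.model.alpha:g}): "
            f"{len(enriched)}",
        ]
        for _, row in enriched.iterrows():
            lines.append(
                f"  cluster {row['cluster']}: {row['direction']} "
                f"(median JSP {row['median_JSP']:.3f} vs "
                f"HCB {row['median_HCB']:.3f}, q={row['q']:.2e})")
        lines.append(f"significant cluster-defining marks: {len(sig)}")
        top = sig.reindex(sig["cohens_d"].abs().sort_values(ascending=False).index)
        for _, row in top.head(8).iterrows():
            lines.append(
                f"  cluster {row['cluster']} / {row['hptm']}: "
                f"d={row['cohens_d']:+.2f}, q={row['q']:.2e}")
        return "\n".join(lines)

    def plot_embedding(self, color: str = "cluster", ax=None):
        """Scatter of the 2-D embedding colored by cluster or group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xy = self.embedding.coords
        if color == "cluster":
            c = self.clusters.labels
        elif color == "group":
            c = pd.factorize(self.subset.group)[0]
        else:
            raise ValidationError("color must be 'cluster' or 'group'")
        ax.scatter(xy[:, 0], xy[:, 1], c=c, s=3, cmap="tab20")
        ax.set_xlabel("UMAP1")
        ax.set_ylabel("UMAP2")
        return ax

    def plot_heatmap(self, ax=None):
        """Cluster x HPTM median heatmap in dendrogram order."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.heatmap.medians.loc[self.heatmap.row_order,
                                     self.heatmap.col_order]
        im = ax.imshow(m.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(m.shape[1]), m.columns, rotation=90)
        ax.set_yticks(range(m.shape[0]),
                      [f"cluster {c}" for c in m.index])
        ax.figure.colorbar(im, ax=ax, label="median residual")
        return ax
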