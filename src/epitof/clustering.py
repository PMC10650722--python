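"""PhenoGraph-style graph clustering on the 2-D embedding.

Construction: exact k-nearest-neighbor graph (Euclidean) on the embedded
coordinates, edges reweighted by the Jaccard overlap of the two
endpoints' neighbor sets, then modularity-maximizing community detection
(Leiden with the modularity objective, seeded for determinism). Cluster
labels are renumbered so that cluster 1 is always the largest.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .embedding import Embedding
from .normalize import ValidationError


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels, 1..K with cluster 1 the largest."""

    labels: np.ndarray
    k_neighbors: int
    seed: int
    modularity: float = float("nan")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if len(uniq) == 0 or uniq[0] != 1 or not np.array_equal(
                uniq, np.arange(1, len(uniq) + 1)):
            raise ValidationError("cluster labels must be contiguous starting at 1")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def cluster_phenograph(points: Embedding | np.ndarray, k: int = 1000,
                       seed: int = 0) -> ClusterAssignment:
    """Cluster embedded cells by Jaccard-kNN community detection.

    ``k`` is the neighborhood size of the kNN graph; it must be smaller
    than the number of cells. The study uses k=1000 on 40,000 cells;
    smaller datasets should scale k down proportionally.
    """
    coords = points.coords if isinstance(points, Embedding) else np.asarray(points, float)
    n = coords.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of cells ({n})")
    if k < 1:
        raise ValidationError("k must be >= 1")

    # Degenerate geometry: with all points coincident there is no
    # neighborhood structure to partition.
    if np.allclose(coords, coords[0]):
        return ClusterAssignment(labels=np.ones(n, dtype=int),
                                 k_neighbors=k, seed=seed, modularity=0.0)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    idx = idx[:, 1:]  # drop self

    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((np.ones(n * k, dtype=np.int32), (rows, idx.ravel())),
                      shape=(n, n))
    adj = ((A + A.T) > 0).astype(np.int32)       # candidate edges (kNN union)
    # shared-neighbor counts on candidate edges; the sparse product costs
    # O(n k^2) while the dense BLAS product costs O(n^3), so dense wins
    # when neighborhoods are a sizable fraction of a moderate dataset
    if k > 0.05 * n and n <= 6000:
        dense = np.zeros((n, n), dtype=np.float32)
        np.put_along_axis(dense, idx, 1.0, axis=1)
        inter = sp.csr_matrix(adj, dtype=np.float32)
        inter.data = np.asarray(
            (dense @ dense.T)[adj.nonzero()]).ravel()
        del dense
    else:
        inter = (A @ A.T).multiply(adj)
    inter = sp.triu(inter, k=1).tocoo()
    union = 2 * k - inter.data
    weights = inter.data / union
    keep = weights > 0
    edges = np.column_stack([inter.row[keep], inter.col[keep]])
    weights = weights[keep]

    graph = ig.Graph(n=n, edges=edges.tolist(), directed=False)
    partition = leidenalg.find_partition(
        graph, leidenalg.ModularityVertexPartition,
        weights=weights.tolist(), seed=seed, n_iterations=-1)
    membership = np.asarray(partition.membership)
    labels = _relabel_by_size(membership)
    return ClusterAssignment(labels=labels, k_neighbors=k, seed=seed,
                             modularity=partition.modularity)


def _relabel_by_size(membership: np.ndarray) -> np.ndarray:
    """Map community ids to 1..K in decreasing size; ties keep original order."""
    ids, counts = np.unique(membership, return_counts=True)
    order = np.lexsort((ids, -counts))
    mapping = np.empty(ids.max() + 1, dtype=int)
    mapping[ids[order]] = np.arange(1, len(ids) + 1)
    return mapping[membership]
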