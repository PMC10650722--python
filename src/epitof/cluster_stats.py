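"""Cluster-level statistics: composition, enrichment and mark signatures.

Given per-cell cluster labels, this module computes per-sample cluster
composition, tests whether each cluster's composition differs between
disease (JSP) and healthy (HCB) samples by Wilcoxon rank-sum with
Benjamini-Hochberg FDR control, and scores cluster-defining HPTMs by
Cohen's D plus rank-sum FDR against all other clusters. It also builds
the cluster x HPTM median matrix with hierarchical dendrogram orderings
used for heatmap display.

A note on attainable significance: with 5 samples per group the exact
two-sided rank-sum p-value can never go below 2/252 ~ 0.0079, which
bounds the significance attainable by any composition comparison at the
study's size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterAssignment
from .containers import GROUP_DISEASE, GROUP_HEALTHY, NormalizedMatrix
from .normalize import ValidationError

log = logging.getLogger(__name__)

#: Smallest exact two-sided rank-sum p attainable with 5 samples per group.
MIN_P_5V5 = 2 / comb(10, 5)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode='exact'`` enumerates the full permutation distribution of the
    midrank sum (a subset-sum dynamic program, so ties are handled
    exactly); ``'normal_approx'`` uses the normal approximation with tie
    and continuity corrections; ``'auto'`` picks exact when both groups
    have <= 10 observations and no tie spans the groups.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test requires two nonempty samples")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "auto":
        cross_ties = bool(set(x) & set(y))
        mode = "exact" if (x.size <= 10 and y.size <= 10 and not cross_ties) \
            else "normal_approx"
    if mode == "exact":
        return _exact_rank_sum(x, y)
    res = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                          use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _exact_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact permutation distribution of the rank sum via subset-sum DP.

    Midranks are multiples of 1/2, so doubling makes them integers; the
    DP counts subsets of each size by doubled rank sum, which is exactly
    the permutation distribution conditioning on the pooled values.
    """
    n, m = len(x), len(y)
    ranks = st.rankdata(np.concatenate([x, y]))
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dp = np.zeros((n + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        for size in range(n, 0, -1):
            dp[size, r:] += dp[size - 1, : total + 1 - r]
    counts = dp[n]
    n_subsets = comb(n + m, n)
    rx2 = int(np.rint(2 * ranks[:n].sum()))
    p_le = counts[: rx2 + 1].sum() / n_subsets
    p_ge = counts[rx2:].sum() / n_subsets
    p = min(1.0, 2.0 * min(p_le, p_ge))
    u = ranks[:n].sum() - n * (n + 1) / 2
    return float(u), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(in_group, out_group) -> float:
    """Standardized mean difference with the pooled standard deviation."""
    a = np.asarray(in_group, dtype=float)
    b = np.asarray(out_group, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("Cohen's D requires >= 2 values per group")
    n1, n2 = a.size, b.size
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise ValidationError("Cohen's D undefined: pooled SD is zero")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def ttest_welch(x, y) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances), two-sided."""
    res = st.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# composition and enrichment
# ---------------------------------------------------------------------------

@dataclass
class CompositionTable:
    """Samples x clusters cell-fraction table with per-sample group labels."""

    proportions: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        rows = self.proportions.to_numpy()
        if (rows < 0).any():
            raise ValidationError("proportions must be nonnegative")
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-12):
            raise ValidationError("each sample's proportions must sum to 1")


def composition_table(assignment: ClusterAssignment, sample_ids,
                      sample_groups: pd.Series) -> CompositionTable:
    """Fraction of each sample's cells in each cluster (absent pairs are 0)."""
    sample_ids = pd.Series(np.asarray(sample_ids, dtype=object), name="sample_id")
    if len(sample_ids) != len(assignment.labels):
        raise ValidationError("sample_ids must align with cluster labels")
    counts = pd.crosstab(sample_ids, pd.Series(assignment.labels, name="cluster"))
    counts = counts.reindex(columns=range(1, assignment.n_clusters + 1), fill_value=0)
    props = counts.div(counts.sum(axis=1), axis=0)
    group = pd.Series(sample_groups).reindex(props.index)
    if group.isna().any():
        raise ValidationError("every sample needs a group label")
    return CompositionTable(proportions=props, group=group)


def cluster_enrichment(table: CompositionTable, alpha: float = 0.05,
                       mode: str = "auto") -> pd.DataFrame:
    """Per-cluster rank-sum test of disease vs healthy composition.

    Returns one row per cluster with group medians, the rank-sum
    statistic, raw p, BH q across clusters, and a direction that is
    ``ns`` unless q < alpha.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    jsp = table.proportions[table.group == GROUP_DISEASE]
    hcb = table.proportions[table.group == GROUP_HEALTHY]
    if len(jsp) < 2 or len(hcb) < 2:
        raise ValidationError("need >= 2 samples in each group")
    rows = []
    for cluster in table.proportions.columns:
        stat, p = wilcoxon_rank_sum(jsp[cluster], hcb[cluster], mode=mode)
        rows.append({"cluster": cluster,
                     "median_JSP": float(jsp[cluster].median()),
                     "median_HCB": float(hcb[cluster].median()),
                     "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"])
    diff = out["median_JSP"] - out["median_HCB"]
    out["direction"] = np.where(
        out["q"] >= alpha, "ns",
        np.where(diff > 0, "JSP-enriched", "HCB-enriched"))
    return out


def cluster_defining_marks(normalized: NormalizedMatrix,
                           assignment: ClusterAssignment,
                           alpha: float = 0.05,
                           family: str = "global",
                           mode: str = "auto") -> pd.DataFrame:
    """Score each (cluster, HPTM) pair against all other clusters.

    Effect size is Cohen's D of in-cluster vs out-of-cluster residuals;
    significance is the rank-sum p with BH correction either across all
    (cluster, HPTM) pairs (``family='global'``, default) or within each
    cluster (``family='per_cluster'``).
    """
    if family not in ("global", "per_cluster"):
        raise ValidationError(f"unknown FDR family {family!r}")
    labels = assignment.labels
    if len(labels) != normalized.n_cells:
        raise ValidationError("assignment must align with the normalized matrix")
    values = normalized.residuals
    rows = []
    for cluster in range(1, assignment.n_clusters + 1):
        mask = labels == cluster
        if mask.sum() < 2:
            log.warning("cluster %d has <2 cells; skipping mark signature", cluster)
            continue
        inside = values[mask]
        outside = values[~mask]
        for hptm in values.columns:
            try:
                d = cohens_d(inside[hptm], outside[hptm])
            except ValidationError:
                d = float("nan")
            _, p = wilcoxon_rank_sum(inside[hptm], outside[hptm], mode=mode)
            rows.append({"cluster": cluster, "hptm": hptm, "cohens_d": d, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValidationError("no cluster with >= 2 cells")
    if family == "global":
        out["q"] = bh_fdr(out["p"])
    else:
        out["q"] = out.groupby("cluster")["p"].transform(lambda p: bh_fdr(p))
    out["significant"] = out["q"] < alpha
    return out


# ---------------------------------------------------------------------------
# heatmap matrix
# ---------------------------------------------------------------------------

@dataclass
class HeatmapMatrix:
    """Cluster x HPTM medians with dendrogram orders and enrichment colors."""

    medians: pd.DataFrame
    row_order: list
    col_order: list
    fold_change: pd.Series
    category: pd.Series


_CATEGORY = {"JSP-enriched": "magenta", "HCB-enriched": "green", "ns": "gray"}


def heatmap_matrix(normalized: NormalizedMatrix, assignment: ClusterAssignment,
                   enrichment: pd.DataFrame,
                   fc_stat: str = "mean") -> HeatmapMatrix:
    """Median residual per (cluster, HPTM) with hierarchical ordering.

    Rows and columns are ordered by average-linkage hierarchical
    clustering on Euclidean distances. The per-cluster annotation is the
    fold change of disease vs healthy composition (group ``fc_stat``,
    mean by default) colored magenta/green/gray by enrichment direction.
    """
    labels = pd.Series(assignment.labels, index=normalized.residuals.index,
                       name="cluster")
    medians = normalized.residuals.groupby(labels).median()
    row_order = [medians.index[i] for i in _linkage_order(medians.to_numpy())]
    col_order = [medians.columns[i] for i in _linkage_order(medians.to_numpy().T)]

    comp = composition_table(
        assignment, normalized.sample_id,
        pd.crosstab(normalized.sample_id, normalized.group).idxmax(axis=1))
    agg = getattr(comp.proportions[comp.group == GROUP_DISEASE], fc_stat)()
    ref = getattr(comp.proportions[comp.group == GROUP_HEALTHY], fc_stat)()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (agg / ref).replace([np.inf, -np.inf], np.nan)
    category = (enrichment.set_index("cluster")["direction"]
                .map(_CATEGORY).reindex(medians.index).fillna("gray"))
    return HeatmapMatrix(medians=medians, row_order=row_order,
                         col_order=col_order,
                         fold_change=fc.reindex(medians.index),
                         category=category)


def _linkage_order(matrix: np.ndarray) -> np.ndarray:
    if matrix.shape[0] < 2:
        return np.arange(matrix.shape[0])
    link = sch.linkage(matrix, method="average", metric="euclidean")
    return sch.leaves_list(link)
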