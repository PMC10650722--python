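"""Differential chromatin accessibility on region x sample count matrices.

The pipeline starts from quantified counts (upstream alignment and peak
calling are done elsewhere): counts are library-size normalized, each
region is tested for a disease-vs-healthy difference with a Welch t-test
on log2(normalized + 1), and regions are called differential by the
joint filter FDR < alpha and |linear fold change| >= min_fc. A TSS
enrichment profile over +/-5000 bp windows is provided as library QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .cluster_stats import bh_fdr, ttest_welch
from .containers import GROUP_DISEASE, GROUP_HEALTHY, normalize_group_labels
from .normalize import ValidationError

log = logging.getLogger(__name__)

REGION_COLUMNS = ("chrom", "start", "end")


@dataclass
class RegionCountMatrix:
    """Regions (0-based half-open BED intervals) x samples read counts."""

    regions: pd.DataFrame
    counts: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if len(self.regions) == 0:
            raise ValidationError("region count matrix has no regions")
        missing = [c for c in REGION_COLUMNS if c not in self.regions.columns]
        if missing:
            raise ValidationError(f"regions table missing column(s): {missing}")
        if (self.regions["start"] >= self.regions["end"]).any():
            raise ValidationError("every region needs start < end")
        keys = self.regions[list(REGION_COLUMNS)].apply(tuple, axis=1)
        if keys.duplicated().any():
            raise ValidationError("region keys must be unique")
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.isfinite(arr).all():
            raise ValidationError("counts must be finite and nonnegative")
        self.group = normalize_group_labels(
            pd.Series(self.group).reindex(self.counts.columns))
        if self.group.isna().any():
            raise ValidationError("every sample column needs a group label")

    @property
    def region_ids(self) -> pd.Series:
        r = self.regions
        return (r["chrom"].astype(str) + ":" + r["start"].astype(str)
                + "-" + r["end"].astype(str))


def read_region_counts(path, groups: dict | pd.Series) -> RegionCountMatrix:
    """Read a BED-like TSV (chrom, start, end, one column per sample)."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in REGION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s): {missing}")
    samples = [c for c in frame.columns if c not in REGION_COLUMNS]
    return RegionCountMatrix(regions=frame[list(REGION_COLUMNS)],
                             counts=frame[samples],
                             group=pd.Series(groups))


def write_region_counts(matrix: RegionCountMatrix, path) -> None:
    pd.concat([matrix.regions, matrix.counts], axis=1).to_csv(
        path, sep="\t", index=False)


def normalize_counts(matrix: RegionCountMatrix,
                     method: str = "median_of_ratios") -> pd.DataFrame:
    """Library-size normalization.

    ``cpm`` scales each sample to one million total counts;
    ``median_of_ratios`` divides by DESeq-style size factors (median of
    per-region ratios to the geometric-mean reference, regions containing
    any zero excluded from the reference).
    """
    counts = matrix.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(matrix.counts.columns[totals == 0])
        raise ValidationError(f"sample(s) with zero total counts: {bad}")
    if method == "cpm":
        normed = counts / totals * 1e6
    elif method == "median_of_ratios":
        positive = (counts > 0).all(axis=1)
        if not positive.any():
            raise ValidationError(
                "median-of-ratios undefined: every region contains a zero")
        log_ref = np.log(counts[positive]).mean(axis=1)
        size = np.exp(np.median(np.log(counts[positive]) - log_ref[:, None], axis=0))
        normed = counts / size
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    return pd.DataFrame(normed, index=matrix.counts.index,
                        columns=matrix.counts.columns)


class DifferentialAccessibility:
    """Model for disease-vs-healthy differential accessibility.

    ``fit()`` normalizes counts, runs a per-region Welch t-test on
    log2(normalized + 1), BH-adjusts across regions and applies the joint
    filter q < ``alpha`` and |linear fold change| >= ``min_fc``.
    """

    def __init__(self, matrix: RegionCountMatrix, alpha: float = 0.05,
                 min_fc: float = 2.0, normalization: str = "median_of_ratios"):
        if not 0 < alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if min_fc < 1:
            raise ValidationError("min_fc must be >= 1")
        n_jsp = int((matrix.group == GROUP_DISEASE).sum())
        n_hcb = int((matrix.group == GROUP_HEALTHY).sum())
        if n_jsp < 2 or n_hcb < 2:
            raise ValidationError("need >= 2 samples per group")
        self.matrix = matrix
        self.alpha = alpha
        self.min_fc = min_fc
        self.normalization = normalization

    def fit(self) -> "DifferentialAccessibilityResults":
        normed = normalize_counts(self.matrix, self.normalization)
        logged = np.log2(normed.to_numpy() + 1.0)
        jsp = logged[:, (self.matrix.group == GROUP_DISEASE).to_numpy()]
        hcb = logged[:, (self.matrix.group == GROUP_HEALTHY).to_numpy()]
        res = st.ttest_ind(jsp, hcb, axis=1, equal_var=False)
        stats, pvals = np.asarray(res.statistic), np.asarray(res.pvalue)
        # A region with identical values in both groups has zero variance
        # and an undefined t statistic; it carries no evidence, so p := 1.
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        log2fc = jsp.mean(axis=1) - hcb.mean(axis=1)
        qvals = bh_fdr(pvals)
        min_l2 = np.log2(self.min_fc)
        status = np.where(
            (qvals < self.alpha) & (log2fc >= min_l2), "up_in_JMML",
            np.where((qvals < self.alpha) & (log2fc <= -min_l2),
                     "down_in_JMML", "ns"))
        table = pd.DataFrame({
            "region": self.matrix.region_ids.to_numpy(),
            "chrom": self.matrix.regions["chrom"].to_numpy(),
            "start": self.matrix.regions["start"].to_numpy(),
            "end": self.matrix.regions["end"].to_numpy(),
            "log2fc": log2fc, "t": stats, "p": pvals, "q": qvals,
            "status": status,
        })
        return DifferentialAccessibilityResults(self, table)


class DifferentialAccessibilityResults:
    """Per-region fold changes, q-values and up/down calls."""

    def __init__(self, model: DifferentialAccessibility, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def n_up(self) -> int:
        return int((self.table["status"] == "up_in_JMML").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["status"] == "down_in_JMML").sum())

    def volcano_table(self) -> pd.DataFrame:
        """One row per region: fold change, -log10 p and call status."""
        with np.errstate(divide="ignore"):
            neg_log10 = -np.log10(self.table["p"].to_numpy())
        return pd.DataFrame({
            "region": self.table["region"],
            "log2fc": self.table["log2fc"],
            "neg_log10_p": neg_log10,
            "status": self.table["status"],
        })

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"up_in_JMML": "tab:red", "down_in_JMML": "tab:blue",
                  "ns": "0.7"}
        v = self.volcano_table()
        for status, sub in v.groupby("status"):
            ax.scatter(sub["log2fc"], sub["neg_log10_p"], s=6,
                       c=colors[status], label=status)
        ax.set_xlabel("log2 fold change (JSP vs HCB)")
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        return "\n".join([
            "Differential accessibility (Welch t on log2 normalized counts)",
            f"  regions: {len(self.table)}   normalization: "
            f"{self.model.normalization}",
            f"  filter: q < {self.model.alpha:g} and |FC| >= "
            f"{self.model.min_fc:g}",
            f"  up in JMML: {self.n_up}   down in JMML: {self.n_down}",
        ])


def differential_regions(matrix: RegionCountMatrix, alpha: float = 0.05,
                         min_fc: float = 2.0,
                         normalization: str = "median_of_ratios"
                         ) -> DifferentialAccessibilityResults:
    """Functional wrapper over :class:`DifferentialAccessibility`."""
    return DifferentialAccessibility(matrix, alpha=alpha, min_fc=min_fc,
                                     normalization=normalization).fit()


# ---------------------------------------------------------------------------
# TSS enrichment QC
# ---------------------------------------------------------------------------

@dataclass
class TssEnrichmentProfile:
    """Mean fragment coverage per position around the TSS, plus a score.

    The score is the mean coverage of the central 100 bp divided by the
    mean of the outer 100-bp flanks; ~1 for uniform background, >>1 for
    TSS-enriched libraries.
    """

    profile: np.ndarray
    score: float
    window: int = 5000
    flank: int = 100


def tss_enrichment(fragments: pd.DataFrame, tss_list: pd.DataFrame,
                   window: int = 5000, flank: int = 100) -> TssEnrichmentProfile:
    """Aggregate fragment coverage in +/-window bp around each TSS.

    ``fragments`` needs columns chrom/start/end (0-based half-open);
    ``tss_list`` needs chrom/pos/strand. Minus-strand windows are flipped
    so that position 0 of the profile is always the upstream edge.
    """
    if len(tss_list) == 0:
        raise ValidationError("TSS list must be nonempty")
    width = 2 * window + 1
    profile = np.zeros(width)
    frag_by_chrom = {c: sub.sort_values("start").reset_index(drop=True)
                     for c, sub in fragments.groupby("chrom")}
    any_overlap = False
    for _, tss in tss_list.iterrows():
        sub = frag_by_chrom.get(tss["chrom"])
        if sub is None:
            continue
        win_start = int(tss["pos"]) - window
        win_end = win_start + width
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        mask = (starts < win_end) & (ends > win_start)
        if not mask.any():
            continue
        any_overlap = True
        diff = np.zeros(width + 1)
        lo = np.clip(starts[mask] - win_start, 0, width)
        hi = np.clip(ends[mask] - win_start, 0, width)
        np.add.at(diff, lo, 1.0)
        np.add.at(diff, hi, -1.0)
        cov = np.cumsum(diff[:-1])
        if tss["strand"] == "-":
            cov = cov[::-1]
        profile += cov
    profile /= len(tss_list)
    flank_cov = np.concatenate([profile[:flank], profile[-flank:]]).mean()
    half = flank // 2
    center_cov = profile[window - half: window + half + 1].mean()
    if not any_overlap:
        log.warning("no fragments overlap any TSS window; score is 0")
        score = 0.0
    elif flank_cov == 0:
        score = 0.0 if center_cov == 0 else float("inf")
    else:
        score = float(center_cov / flank_cov)
    return TssEnrichmentProfile(profile=profile, score=score,
                                window=window, flank=flank)
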