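import numpy as np
import pandas as pd
import pytest

from epitof import (DifferentialAccessibility, RegionCountMatrix,
                    differential_regions, normalize_counts,
                    simulate_region_counts, tss_enrichment)
from epitof.cluster_stats import bh_fdr
from epitof.normalize import ValidationError


def _matrix(counts, groups):
    counts = pd.DataFrame(counts)
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    n = len(counts)
    regions = pd.DataFrame({"chrom": "chr1",
                            "start": np.arange(n) * 100,
                            "end": np.arange(n) * 100 + 50})
    return RegionCountMatrix(regions=regions, counts=counts,
                             group=pd.Series(groups, index=counts.columns))


class TestNormalizeCounts:
    def test_cpm_direct_scaling(self):
        m = _matrix([[200], [2_000_000 - 200]], ["HCB"])
        # need two groups for the container? group validation maps labels only
        cpm = normalize_counts(m, method="cpm")
        assert cpm.iloc[0, 0] == pytest.approx(100.0)

    def test_identical_samples_have_unit_size_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, 50)
        m = _matrix(np.column_stack([col, col]), ["HCB", "JSP"])
        mor = normalize_counts(m, method="median_of_ratios")
        np.testing.assert_allclose(mor.to_numpy()[:, 0], col)
        np.testing.assert_allclose(mor.to_numpy()[:, 1], col)

    def test_cpm_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 500, size=(30, 2))
        m1 = _matrix(counts, ["HCB", "JSP"])
        doubled = counts.copy()
        doubled[:, 1] *= 2
        m2 = _matrix(doubled, ["HCB", "JSP"])
        np.testing.assert_allclose(
            normalize_counts(m1, "cpm").iloc[:, 1],
            normalize_counts(m2, "cpm").iloc[:, 1])

    def test_all_zero_sample_rejected(self):
        m = _matrix([[1, 0], [2, 0]], ["HCB", "JSP"])
        with pytest.raises(ValidationError, match="zero total"):
            normalize_counts(m, "cpm")


class TestDifferentialRegions:
    def _toy(self):
        """Six regions with hand-chosen counts, 3 HCB + 3 JSP samples."""
        hcb = np.array([
            [100, 110, 90],    # strong up in JSP
            [100, 105, 95],    # unchanged
            [400, 420, 380],   # strong down in JSP
            [100, 101, 99],    # small shift, below fold-change filter
            [50, 500, 5],      # huge variance: not significant
            [200, 210, 190],   # unchanged
        ])
        jsp = np.array([
            [400, 430, 390],
            [101, 99, 100],
            [100, 95, 105],
            [150, 152, 148],
            [500, 5, 50],
            [205, 195, 200],
        ])
        return _matrix(np.column_stack([hcb, jsp]),
                       ["HCB"] * 3 + ["JSP"] * 3)

    def test_toy_matrix_matches_brute_force_filter(self):
        m = self._toy()
        res = DifferentialAccessibility(m, normalization="cpm").fit()
        table = res.table
        # independent re-application of the joint filter
        expected = np.where(
            (bh_fdr(table["p"]) < 0.05) & (np.abs(table["log2fc"]) >= 1),
            np.where(table["log2fc"] > 0, "up_in_JMML", "down_in_JMML"), "ns")
        np.testing.assert_array_equal(table["status"].to_numpy(), expected)
        assert res.n_up == 1 and res.n_down == 1
        assert table.loc[0, "status"] == "up_in_JMML"
        assert table.loc[2, "status"] == "down_in_JMML"
        assert table.loc[3, "status"] == "ns"  # significant but |FC| < 2
        assert table.loc[4, "status"] == "ns"  # large FC but not significant

    def test_label_swap_symmetry(self):
        m, _ = simulate_region_counts(300, 5, 0.2, 2.5, 0.05, seed=0)
        res = differential_regions(m)
        swapped = RegionCountMatrix(
            regions=m.regions, counts=m.counts,
            group=m.group.map({"HCB": "JSP", "JSP": "HCB"}))
        res_swapped = differential_regions(swapped)
        assert res.n_up == res_swapped.n_down
        assert res.n_down == res_swapped.n_up
        np.testing.assert_allclose(res.table["log2fc"],
                                   -res_swapped.table["log2fc"], atol=1e-10)

    def test_identical_groups_all_ns(self):
        rng = np.random.default_rng(2)
        col = rng.integers(50, 500, 20)
        m = _matrix(np.column_stack([col] * 4), ["HCB", "HCB", "JSP", "JSP"])
        res = differential_regions(m)
        assert res.n_up == 0 and res.n_down == 0
        assert (res.table["status"] == "ns").all()

    def test_too_few_samples_per_group(self):
        m = _matrix([[1, 2, 3]], ["HCB", "JSP", "JSP"])
        with pytest.raises(ValidationError, match=">= 2 samples"):
            DifferentialAccessibility(m)

    def test_volcano_table_shape_and_closed_forms(self):
        m, _ = simulate_region_counts(100, 4, 0.1, 2.0, 0.1, seed=1)
        res = differential_regions(m)
        v = res.volcano_table()
        assert len(v) == 100
        assert (v.loc[res.table["p"] == 1.0, "neg_log10_p"] == 0).all()
        assert set(v["status"]) <= {"up_in_JMML", "down_in_JMML", "ns"}


class TestTssEnrichment:
    def test_uniform_fragments_score_near_one(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 20_000, 50_000)
        frags = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + 200})
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000],
                            "strand": ["+"]})
        prof = tss_enrichment(frags, tss)
        assert prof.score == pytest.approx(1.0, rel=0.1)
        assert len(prof.profile) == 10_001

    def test_fragments_centered_on_tss_score_high(self):
        frags = pd.DataFrame({"chrom": "chr1",
                              "start": np.full(500, 9_950),
                              "end": np.full(500, 10_050)})
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000],
                            "strand": ["+"]})
        prof = tss_enrichment(frags, tss)
        assert prof.score > 100

    def test_minus_strand_profile_is_mirrored(self):
        frags = pd.DataFrame({"chrom": "chr1",
                              "start": [11_000, 11_000, 12_000],
                              "end": [11_300, 11_300, 12_100]})
        plus = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000],
                             "strand": ["+"]})
        minus = plus.assign(strand="-")
        p_plus = tss_enrichment(frags, plus).profile
        p_minus = tss_enrichment(frags, minus).profile
        np.testing.assert_array_equal(p_minus, p_plus[::-1])

    def test_no_overlap_warns_and_scores_zero(self, caplog):
        frags = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100]})
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000],
                            "strand": ["+"]})
        with caplog.at_level("WARNING"):
            prof = tss_enrichment(frags, tss)
        assert prof.score == 0.0
        assert "no fragments" in caplog.text

    def test_empty_tss_list_rejected(self):
        with pytest.raises(ValidationError):
            tss_enrichment(pd.DataFrame({"chrom": [], "start": [], "end": []}),
                           pd.DataFrame({"chrom": [], "pos": [], "strand": []}))
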