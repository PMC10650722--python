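"""Statistical primitives checked against independent brute-force oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from epitof import (ClusterAssignment, NormalizedMatrix, bh_fdr,
                    cluster_defining_marks, cluster_enrichment, cohens_d,
                    composition_table, heatmap_matrix, wilcoxon_rank_sum)
from epitof.cluster_stats import CompositionTable, MIN_P_5V5
from epitof.normalize import ValidationError


def rank_sum_permutation_oracle(x, y):
    """Exhaustive two-sided permutation p for the rank-sum statistic."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = len(x)
    observed = ranks[:n].sum()
    sums = np.array([sum(ranks[list(c)])
                     for c in combinations(range(len(pooled)), n)])
    p_le = np.mean(sums <= observed + 1e-9)
    p_ge = np.mean(sums >= observed - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


def bh_stepup_oracle(p):
    """Direct BH step-up formula with the monotonicity pass."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestWilcoxonRankSum:
    def test_textbook_example(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)
        assert stat == 0.0

    def test_five_vs_five_complete_separation_floor(self):
        _, p = wilcoxon_rank_sum([0.6, 0.62, 0.58, 0.61, 0.59],
                                 [0.1, 0.12, 0.09, 0.11, 0.1])
        assert p == pytest.approx(2 / comb(10, 5), abs=1e-12)
        assert p == pytest.approx(MIN_P_5V5)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="exact")
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("tied", [False, True])
    def test_exact_matches_exhaustive_permutation(self, seed, tied):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 9, size=2)
        if tied:
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, m).astype(float)
        else:
            x, y = rng.normal(size=n), rng.normal(size=m)
        _, p = wilcoxon_rank_sum(x, y, mode="exact")
        assert p == pytest.approx(rank_sum_permutation_oracle(x, y), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    def test_auto_switches_to_approximation_for_large_samples(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(1.0, 1.0, size=50)
        _, p_auto = wilcoxon_rank_sum(x, y, mode="auto")
        _, p_approx = wilcoxon_rank_sum(x, y, mode="normal_approx")
        assert p_auto == p_approx


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.002, 0.01, 0.03, 0.04]),
                                   [0.008, 0.02, 0.04, 0.04], atol=1e-12)

    def test_all_ones_capped(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_stepup_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(bh_fdr(p), bh_stepup_oracle(p), atol=1e-12)

    def test_q_never_below_p_and_monotone(self):
        rng = np.random.default_rng(99)
        p = rng.uniform(size=25)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestCohensD:
    def test_worked_example(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_equal_means_give_zero(self):
        assert cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(0.5, 1, size=12)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValidationError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


def _assignment(labels):
    return ClusterAssignment(labels=np.asarray(labels), k_neighbors=0, seed=0)


class TestComposition:
    def test_direct_count(self):
        comp = composition_table(_assignment([1, 1, 2, 2]),
                                 ["s", "s", "s", "s"],
                                 pd.Series({"s": "HCB"}))
        np.testing.assert_allclose(comp.proportions.loc["s"], [0.5, 0.5])

    def test_absent_cluster_is_zero(self):
        comp = composition_table(_assignment([1, 1, 2, 3]),
                                 ["a", "a", "a", "b"],
                                 pd.Series({"a": "HCB", "b": "JSP"}))
        assert comp.proportions.loc["a", 3] == 0.0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 5, 100)
        labels[:4] = [1, 2, 3, 4]
        ids = rng.choice(["a", "b", "c"], 100)
        comp = composition_table(
            _assignment(labels), ids,
            pd.Series({"a": "HCB", "b": "JSP", "c": "HCB"}))
        np.testing.assert_allclose(comp.proportions.sum(axis=1), 1.0)


class TestEnrichment:
    def _table(self, jsp_a, hcb_a):
        props = pd.DataFrame({
            1: np.concatenate([jsp_a, hcb_a]),
            2: 1 - np.concatenate([jsp_a, hcb_a])})
        props.index = [f"J{i}" for i in range(len(jsp_a))] + \
                      [f"H{i}" for i in range(len(hcb_a))]
        group = pd.Series(["JSP"] * len(jsp_a) + ["HCB"] * len(hcb_a),
                          index=props.index)
        return CompositionTable(proportions=props, group=group)

    def test_complete_separation_flagged_with_exact_floor_p(self):
        table = self._table(np.array([0.6, 0.62, 0.58, 0.61, 0.59]),
                            np.array([0.1, 0.12, 0.09, 0.11, 0.1]))
        res = cluster_enrichment(table)
        row = res[res["cluster"] == 1].iloc[0]
        assert row["p"] == pytest.approx(2 / 252)
        assert row["direction"] == "JSP-enriched"
        other = res[res["cluster"] == 2].iloc[0]
        assert other["direction"] == "HCB-enriched"

    def test_direction_matches_median_difference_sign(self):
        rng = np.random.default_rng(1)
        table = self._table(rng.uniform(0.4, 0.9, 5), rng.uniform(0.0, 0.4, 5))
        res = cluster_enrichment(table)
        for _, row in res.iterrows():
            if row["direction"] == "JSP-enriched":
                assert row["median_JSP"] > row["median_HCB"]
            elif row["direction"] == "HCB-enriched":
                assert row["median_JSP"] < row["median_HCB"]

    def test_one_group_too_small(self):
        table = self._table(np.array([0.5]), np.array([0.4, 0.5, 0.6]))
        with pytest.raises(ValidationError):
            cluster_enrichment(table)


class TestClusterDefiningMarks:
    def _normalized(self, values, panel):
        return NormalizedMatrix(
            residuals=pd.DataFrame(values, columns=list(panel.hptm_markers)),
            sample_id=pd.Series(["s"] * len(values)),
            group=pd.Series(["HCB"] * len(values)), panel=panel)

    def test_mirrored_shifts_have_opposite_signs(self, small_panel):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(200, 3))
        base[:100, 0] += 2.0
        base[100:, 0] -= 2.0
        norm = self._normalized(base, small_panel)
        sig = cluster_defining_marks(norm, _assignment([1] * 100 + [2] * 100))
        d1 = sig[(sig.cluster == 1) & (sig.hptm == "M1")]["cohens_d"].iloc[0]
        d2 = sig[(sig.cluster == 2) & (sig.hptm == "M1")]["cohens_d"].iloc[0]
        assert d1 > 0 > d2
        assert d1 == pytest.approx(-d2, rel=1e-9)

    def test_planted_negative_shift_recovered(self, small_panel):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(300, 3))
        labels = np.array([1] * 150 + [2] * 150)
        base[labels == 2, 1] -= 3.0  # -3 SD shift on M2 in cluster 2
        sig = cluster_defining_marks(self._normalized(base, small_panel),
                                     _assignment(labels))
        row = sig[(sig.cluster == 2) & (sig.hptm == "M2")].iloc[0]
        assert row["cohens_d"] < -2
        assert row["significant"]

    def test_per_cluster_family_option(self, small_panel):
        rng = np.random.default_rng(2)
        norm = self._normalized(rng.normal(size=(90, 3)), small_panel)
        labels = _assignment([1] * 30 + [2] * 30 + [3] * 30)
        glob = cluster_defining_marks(norm, labels, family="global")
        per = cluster_defining_marks(norm, labels, family="per_cluster")
        assert (glob["p"] == per["p"]).all()
        assert not (glob["q"] == per["q"]).all()


class TestHeatmap:
    def _inputs(self, small_panel, values, labels, groups=None):
        n = len(values)
        norm = NormalizedMatrix(
            residuals=pd.DataFrame(values, columns=list(small_panel.hptm_markers)),
            sample_id=pd.Series([f"s{i % 4}" for i in range(n)]),
            group=pd.Series((groups or ["HCB", "HCB", "JSP", "JSP"]
                             )[i % 4] for i in range(n)),
            panel=small_panel)
        enr = pd.DataFrame({"cluster": sorted(set(labels)),
                            "direction": "ns"})
        return norm, _assignment(labels), enr

    def test_constant_matrix_degenerates_gracefully(self, small_panel):
        norm, asg, enr = self._inputs(small_panel, np.full((40, 3), 2.0),
                                      [1, 2] * 20)
        heat = heatmap_matrix(norm, asg, enr)
        assert (heat.medians.to_numpy() == 2.0).all()
        assert sorted(heat.row_order) == [1, 2]
        assert (heat.category == "gray").all()

    def test_median_of_constant_cluster_is_exact(self, small_panel):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(40, 3))
        labels = np.array([1, 2] * 20)
        values[labels == 2, 1] = 2.0
        norm, asg, enr = self._inputs(small_panel, values, labels)
        heat = heatmap_matrix(norm, asg, enr)
        assert heat.medians.loc[2, "M2"] == 2.0

    def test_orders_are_permutations(self, small_panel):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 5, 100)
        labels[:4] = [1, 2, 3, 4]
        norm, asg, enr = self._inputs(small_panel,
                                      rng.normal(size=(100, 3)), labels)
        heat = heatmap_matrix(norm, asg, enr)
        assert sorted(heat.row_order) == [1, 2, 3, 4]
        assert sorted(heat.col_order) == sorted(small_panel.hptm_markers)
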