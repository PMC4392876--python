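"""Correlation ranking, clustering, group statistics and knockdown tests."""

import numpy as np
import pandas as pd
import pytest

from cistromix.stats import (
    anchor_correlation,
    boxplot_summary,
    hierarchical_cluster,
    knockdown_test,
    log2_counts,
    mannwhitney,
    partition_foxm1,
    significance_mark,
    venn_overlap,
)


def expr_frame(rows: dict, samples=None) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    if samples:
        df.columns = samples
    return df


class TestAnchorCorrelation:
    def test_linear_gene_flagged(self):
        m = expr_frame({"FOXM1": [1, 2, 3, 4], "y": [2, 4, 6, 8]})
        results, order = anchor_correlation(m, "FOXM1")
        by_id = {r.gene_id: r for r in results}
        assert by_id["y"].r == pytest.approx(1.0)
        assert by_id["y"].passes_threshold

    def test_anticorrelated_not_flagged(self):
        m = expr_frame({"FOXM1": [1, 2, 3, 4], "y": [-1, -2, -3, -4]})
        results, _ = anchor_correlation(m, "FOXM1")
        by_id = {r.gene_id: r for r in results}
        assert by_id["y"].r == pytest.approx(-1.0)
        assert not by_id["y"].passes_threshold

    def test_threshold_is_strict(self):
        m = expr_frame({"FOXM1": [1, 2, 3, 4], "y": [2, 4, 6, 8]})
        results, _ = anchor_correlation(m, "FOXM1", threshold=1.0)
        assert not {r.gene_id: r for r in results}["y"].passes_threshold

    def test_independent_noise_small_r(self, rng):
        n = 1000
        m = expr_frame({"FOXM1": rng.normal(size=n), "y": rng.normal(size=n)})
        results, _ = anchor_correlation(m, "FOXM1")
        assert abs({r.gene_id: r for r in results}["y"].r) < 0.1

    def test_sample_order_by_ascending_anchor(self):
        m = expr_frame({"FOXM1": [3, 1, 2]}, samples=["a", "b", "c"])
        _, order = anchor_correlation(
            expr_frame({"FOXM1": [3, 1, 2], "y": [1, 2, 3]}, samples=["a", "b", "c"]),
            "FOXM1",
        )
        assert order == ["b", "c", "a"]

    def test_zero_variance_gene_skipped_with_warning(self, caplog):
        import logging

        m = expr_frame({"FOXM1": [1, 2, 3], "flat": [5, 5, 5]})
        with caplog.at_level(logging.WARNING):
            results, _ = anchor_correlation(m, "FOXM1")
        assert "flat" not in {r.gene_id for r in results}
        assert "zero variance" in caplog.text

    def test_missing_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            anchor_correlation(expr_frame({"y": [1, 2, 3]}), "FOXM1")

    def test_log2_recovers_planted_log_scale_correlation(self, rng):
        # multiplicative (log-normal) data: Pearson on the log2 scale sees
        # the planted correlation that raw-count Pearson attenuates
        n = 78
        z = rng.normal(size=n)
        anchor = np.exp(1 + 0.8 * z)
        gene = np.exp(2 + 0.8 * (0.8 * z + 0.6 * rng.normal(size=n)))
        m = expr_frame({"FOXM1": anchor, "y": gene})
        results, _ = anchor_correlation(log2_counts(m), "FOXM1")
        assert {r.gene_id: r for r in results}["y"].r == pytest.approx(0.8, abs=0.15)


class TestHierarchicalCluster:
    def test_identical_genes_merge_first(self):
        m = expr_frame(
            {"a": [1, 2, 3, 4], "b": [2, 4, 6, 8], "c": [4, 1, 3, 2]}
        )
        linkage, leaves = hierarchical_cluster(m, axis="genes")
        # a and b are perfectly correlated: first merge at height 0
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(leaves[:2]) == {"a", "b"} or set(leaves[-2:]) == {"a", "b"}

    def test_anticorrelated_distance_two(self):
        m = expr_frame({"a": [1, 2, 3], "b": [3, 2, 1]})
        linkage, _ = hierarchical_cluster(m)
        assert linkage[0, 2] == pytest.approx(2.0)

    def test_planted_pair_merges_before_independent(self, rng):
        noise = rng.normal(size=20)
        m = expr_frame(
            {"g1": noise, "g2": noise * 2 + 1, "g3": rng.normal(size=20)}
        )
        linkage, _ = hierarchical_cluster(m)
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_samples_axis(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        _, leaves = hierarchical_cluster(m, axis="samples")
        assert sorted(leaves) == list("abcd")

    def test_zero_variance_item_rejected(self):
        m = expr_frame({"a": [1, 2, 3], "flat": [1, 1, 1]})
        with pytest.raises(ValueError, match="flat"):
            hierarchical_cluster(m)


class TestMannWhitney:
    def test_exact_small_sample(self):
        # all C(4,2)=6 labelings; U_A = 0 is one extreme -> two-sided 2/6
        res = mannwhitney([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        res = mannwhitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_all_constant_degenerate(self):
        res = mannwhitney([5, 5], [5, 5])
        assert res.p_value == 1.0

    def test_large_shift_detected(self, rng):
        a = rng.normal(0, 1, size=30)
        b = rng.normal(3, 1, size=30)
        res = mannwhitney(a, b)
        assert res.p_value < 0.01
        assert res.significance_mark == "**"

    def test_fold_change_is_median_ratio(self):
        res = mannwhitney([1, 2, 3], [2, 4, 6])
        assert res.fold_change == pytest.approx(2.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney([], [1, 2])

    def test_null_calibration_at_study_sizes(self, rng):
        # at the 24-normal / 58-tumour design, the rejection rate under the
        # null must sit near the nominal 5% level
        n_sim = 600
        rejections = sum(
            mannwhitney(rng.normal(size=24), rng.normal(size=58)).p_value < 0.05
            for _ in range(n_sim)
        )
        assert 0.02 < rejections / n_sim < 0.09


class TestBoxplotSummary:
    def test_zero_iqr_outlier(self):
        s = boxplot_summary([0, 0, 0, 0, 10])
        assert s.q1 == s.q3 == 0
        assert s.outliers == [10.0]

    def test_symmetric_no_outliers(self):
        s = boxplot_summary([1, 2, 3, 4, 5, 6, 7])
        assert s.outliers == []
        assert s.median == 4

    def test_all_equal_no_outliers(self):
        s = boxplot_summary([3, 3, 3, 3])
        assert s.iqr == 0 and s.outliers == []

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            boxplot_summary([1, 2, 3])

    def test_fences_strict(self):
        # values exactly AT the fence are not outliers
        values = [0, 2, 4, 6, 8]  # q1=2, q3=6, iqr=4 -> fences at -4 and 12
        s = boxplot_summary(values + [12, -4])
        assert 12.0 not in s.outliers and -4.0 not in s.outliers


class TestPartition:
    def test_hand_arithmetic(self):
        # normals mean 10, sd 2: high needs > 14 AND > 20
        labels = partition_foxm1([21, 15], [8, 10, 12])
        assert list(labels) == ["high", "low"]

    def test_exact_twofold_is_low(self):
        labels = partition_foxm1([20], [8, 10, 12])
        assert list(labels) == ["low"]

    def test_scale_invariance(self, rng):
        normals = rng.lognormal(2, 0.5, size=24)
        tumours = rng.lognormal(2.5, 0.8, size=58)
        base = list(partition_foxm1(tumours, normals))
        for k in (0.001, 7.3, 1e4):
            assert list(partition_foxm1(tumours * k, normals * k)) == base

    def test_too_few_normals_rejected(self):
        with pytest.raises(ValueError):
            partition_foxm1([5], [10])


class TestKnockdownTest:
    def test_textbook_example(self):
        res = knockdown_test([10, 12, 14], [4, 6, 8])
        assert res.statistic == pytest.approx(3.674, abs=1e-3)
        assert res.p_value == pytest.approx(0.0213, abs=1e-3)
        assert res.fold_change == pytest.approx(0.5)

    def test_identical_arms(self):
        res = knockdown_test([5, 6, 7], [5, 6, 7])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.fold_change == pytest.approx(1.0)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            knockdown_test([5, 5, 5], [10, 10, 10])

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            knockdown_test([5], [1, 2])

    def test_agrees_with_textbook_formula(self, rng):
        for _ in range(50):
            c = rng.normal(10, 2, size=int(rng.integers(2, 8)))
            t = rng.normal(8, 2, size=int(rng.integers(2, 8)))
            res = knockdown_test(c, t)
            n1, n2 = len(c), len(t)
            sp2 = ((n1 - 1) * c.var(ddof=1) + (n2 - 1) * t.var(ddof=1)) / (n1 + n2 - 2)
            expected = (c.mean() - t.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            assert res.statistic == pytest.approx(expected, abs=1e-10)


class TestVenn:
    def test_discordant_flagged(self):
        venn = venn_overlap(
            [("a", "up"), ("b", "up"), ("c", "down")],
            [("b", "up"), ("c", "up"), ("d", "down")],
        )
        assert venn.shared == {"b", "c"}
        assert venn.discordant == {"c"}
        assert venn.a_only == {"a"} and venn.b_only == {"d"}

    def test_disjoint(self):
        venn = venn_overlap([("a", "up")], [("b", "down")])
        assert venn.shared == set() and venn.discordant == set()

    def test_identical(self):
        pairs = [("a", "up"), ("b", "down")]
        venn = venn_overlap(pairs, pairs)
        assert venn.shared == {"a", "b"} and not venn.discordant


def test_significance_marks():
    assert significance_mark(0.005) == "**"
    assert significance_mark(0.03) == "*"
    assert significance_mark(0.2) == ""
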