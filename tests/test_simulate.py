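"""Seeded generators: determinism and planted ground truth recovery."""

import numpy as np
import pandas as pd
import pytest

from cistromix.nanostring import normalise
from cistromix.peaks import replicate_consensus
from cistromix.simulate import (
    ExpressionPlan,
    KnockdownPlan,
    PeakPlan,
    SimulationConfig,
    simulate_expression,
    simulate_knockdown,
    simulate_peak_replicates,
    simulate_tags,
)
from cistromix.stats import anchor_correlation, knockdown_test, log2_counts
from cistromix.nanostring import fold_to_normal_median


def peaks_as_tuples(ps):
    return [(p.chrom, p.start, p.end, p.summit, p.fdr, p.tag_density) for p in ps]


class TestPeakReplicates:
    def test_planned_consensus_count_recovered(self):
        cfg = SimulationConfig(seed=11)
        rep1, rep2, truth = simulate_peak_replicates(cfg)
        planned = int(truth.expected_consensus.sum())
        assert planned == cfg.peaks.n_consensus_pairs
        result = replicate_consensus(rep1, rep2)
        assert result.n_high_confidence == planned

    def test_all_low_overlap_yields_nothing(self):
        cfg = SimulationConfig(seed=3)
        cfg.peaks = PeakPlan(
            n_consensus_pairs=0, n_low_overlap_pairs=15, n_gate_fail_pairs=0,
            n_unique_per_set=5, failing_overlap=(0.3, 0.49),
        )
        rep1, rep2, truth = simulate_peak_replicates(cfg)
        assert not truth.expected_consensus.any()
        assert replicate_consensus(rep1, rep2).n_high_confidence == 0

    def test_seed_determinism(self):
        a = simulate_peak_replicates(SimulationConfig(seed=5))
        b = simulate_peak_replicates(SimulationConfig(seed=5))
        assert peaks_as_tuples(a[0]) == peaks_as_tuples(b[0])
        assert peaks_as_tuples(a[1]) == peaks_as_tuples(b[1])
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_different_seeds_differ(self):
        a = simulate_peak_replicates(SimulationConfig(seed=5))
        b = simulate_peak_replicates(SimulationConfig(seed=6))
        assert peaks_as_tuples(a[0]) != peaks_as_tuples(b[0])

    def test_infeasible_plan_rejected(self):
        cfg = SimulationConfig(seed=0, genome={"chr1": 10_000})
        with pytest.raises(ValueError, match="infeasible"):
            simulate_peak_replicates(cfg)


class TestTags:
    def test_zero_background_tags_near_summits(self):
        cfg = SimulationConfig(seed=2)
        cfg.tags.background_rate = 0.0
        rep1, _, _ = simulate_peak_replicates(cfg)
        tags = simulate_tags(cfg, rep1)
        summits = {p.chrom: [] for p in rep1}
        for p in rep1:
            summits[p.chrom].append(p.summit)
        for chrom, positions in tags.items():
            if not len(positions):
                continue
            s = np.asarray(summits.get(chrom, []))
            # every tag within 5 sd of some summit
            dist = np.min(np.abs(positions[:, None] - s[None, :]), axis=1)
            assert (dist <= 5 * cfg.tags.enrichment_sd).all()

    def test_zero_enrichment_flat(self):
        cfg = SimulationConfig(seed=4)
        cfg.tags.tags_per_peak = 0.0
        cfg.tags.background_rate = 0.002
        rep1, _, _ = simulate_peak_replicates(cfg)
        tags = simulate_tags(cfg, rep1)
        # counts in 10 kb windows follow Poisson(20): all within 6 sd
        for chrom, positions in tags.items():
            hist, _ = np.histogram(
                positions, bins=np.arange(0, cfg.genome[chrom] + 1, 10_000)
            )
            lam = cfg.tags.background_rate * 10_000
            assert (np.abs(hist - lam) < 6 * np.sqrt(lam) + 1).all()

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=8)
        rep1, _, _ = simulate_peak_replicates(cfg)
        t1 = simulate_tags(cfg, rep1)
        t2 = simulate_tags(cfg, rep1)
        for chrom in t1:
            assert np.array_equal(t1[chrom], t2[chrom])


class TestExpression:
    def test_planted_r1_zero_noise_recovered_exactly(self):
        cfg = SimulationConfig(seed=9)
        cfg.expression = ExpressionPlan(
            n_correlated=5, planted_r=1.0, n_anticorrelated=0, n_null=0,
            reference_cv=0.0, technical_sd=0.0, content_sd=0.0, stage_folds={},
        )
        cm, truth = simulate_expression(cfg)
        norm = normalise(cm)
        results, _ = anchor_correlation(log2_counts(norm.endogenous), "FOXM1")
        for r in results:
            if r.gene_id.startswith("COR"):
                assert r.r == pytest.approx(1.0, abs=2e-3)  # rounding only

    def test_planted_tumour_fold_zero_noise(self):
        cfg = SimulationConfig(seed=10)
        cfg.expression = ExpressionPlan(
            n_correlated=0, n_anticorrelated=0, n_null=0, log_noise_sd=0.0,
            reference_cv=0.0, technical_sd=0.0, content_sd=0.0, stage_folds={},
            tumour_folds={"MYGENE": 2.0},
        )
        cm, _ = simulate_expression(cfg)
        norm = normalise(cm)
        normals = norm.sample_meta.index[norm.sample_meta.group == "normal"]
        folds = fold_to_normal_median(norm.endogenous, list(normals))
        tumours = norm.sample_meta.index[norm.sample_meta.group == "OAC"]
        assert np.allclose(folds.loc["MYGENE", tumours], 2.0)
        assert np.allclose(folds.loc["MYGENE", normals], 1.0)

    def test_study_design_defaults(self):
        cm, truth = simulate_expression(SimulationConfig(seed=1))
        meta = cm.sample_meta
        assert (meta.group == "normal").sum() == 24
        assert (meta.group == "OAC").sum() == 58
        assert set(truth.kind) >= {"anchor", "correlated", "reference",
                                   "positive_control"}

    def test_anticorrelated_genes_negative_r(self):
        cfg = SimulationConfig(seed=12)
        cm, _ = simulate_expression(cfg)
        norm = normalise(cm)
        results, _ = anchor_correlation(log2_counts(norm.endogenous), "FOXM1")
        antis = [r.r for r in results if r.gene_id.startswith("ANT")]
        assert all(r < 0 for r in antis)

    def test_seed_determinism(self):
        a, ta = simulate_expression(SimulationConfig(seed=13))
        b, tb = simulate_expression(SimulationConfig(seed=13))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(ta, tb)

    def test_too_few_normals_rejected(self):
        cfg = SimulationConfig(seed=0)
        cfg.expression.n_normal = 1
        with pytest.raises(ValueError, match="normal"):
            simulate_expression(cfg)


class TestKnockdown:
    def test_large_effects_detected_and_null_rarely(self):
        detected = {"effect": 0, "null": 0, "n_effect": 0, "n_null": 0}
        for seed in range(30):
            cm, truth = simulate_knockdown(SimulationConfig(seed=seed))
            expr = cm.endogenous
            ntc = [c for c in expr.columns if c.startswith("siNTC")]
            for _, row in truth.iterrows():
                arm_cols = [c for c in expr.columns if c.startswith(row.arm)]
                res = knockdown_test(
                    expr.loc[row.probe_id, ntc], expr.loc[row.probe_id, arm_cols]
                )
                big = abs(row.log2_effect) >= 0.8
                if big:
                    detected["n_effect"] += 1
                    detected["effect"] += res.p_value < 0.05
                elif row.log2_effect == 0:
                    detected["n_null"] += 1
                    detected["null"] += res.p_value < 0.05
        assert detected["effect"] / detected["n_effect"] > 0.8
        assert detected["null"] / detected["n_null"] < 0.15  # near nominal alpha

    def test_directions_match_truth(self):
        cm, truth = simulate_knockdown(SimulationConfig(seed=21))
        expr = cm.endogenous
        ntc = [c for c in expr.columns if c.startswith("siNTC")]
        for _, row in truth[truth.log2_effect.abs() >= 0.8].iterrows():
            arm_cols = [c for c in expr.columns if c.startswith(row.arm)]
            fold = expr.loc[row.probe_id, arm_cols].mean() / expr.loc[
                row.probe_id, ntc
            ].mean()
            assert (fold > 1) == (row.direction == "up")

    def test_seed_determinism(self):
        a, ta = simulate_knockdown(SimulationConfig(seed=2))
        b, tb = simulate_knockdown(SimulationConfig(seed=2))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(ta, tb)


class TestConfig:
    def test_from_dict_round_trip(self):
        cfg = SimulationConfig.from_dict(
            {"seed": 7, "peaks": {"n_consensus_pairs": 3},
             "expression": {"n_normal": 4, "n_tumour": 6}}
        )
        assert cfg.seed == 7
        assert cfg.peaks.n_consensus_pairs == 3
        assert cfg.expression.n_normal == 4

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config key"):
            SimulationConfig.from_dict({"peaks": {"bogus": 1}})
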