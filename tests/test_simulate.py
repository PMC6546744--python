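import numpy as np
import pandas as pd
import pytest

from betimed.dependency import aggregate_gene_scores, compute_guide_lfc
from betimed.rescue import compute_orf_lfc, concordance
from betimed.simulate import (
    BarcodeSimConfig,
    ChipSimConfig,
    CrisprSimConfig,
    DoseResponseSimConfig,
    ExpressionSimConfig,
    OrfSimConfig,
    StudyConfig,
    simulate_barcode_experiment,
    simulate_chip_reads,
    simulate_crispr_screen,
    simulate_dose_response,
    simulate_expression,
    simulate_orf_screen,
    simulate_study,
)
from betimed.synergy import DoseMatrix, bliss_excess


SMALL_CRISPR = CrisprSimConfig(n_genes=300, n_control_guides=100, seed=11)


class TestDeterminism:
    @pytest.mark.parametrize(
        "factory",
        [
            lambda: simulate_crispr_screen(SMALL_CRISPR)[0].counts,
            lambda: simulate_orf_screen(OrfSimConfig(n_orfs=200, seed=3))[0].counts,
            lambda: simulate_expression(ExpressionSimConfig(n_genes=100, seed=5))[0].to_numpy(),
            lambda: simulate_barcode_experiment(BarcodeSimConfig(n_barcodes=500, seed=7))[0].counts,
            lambda: simulate_dose_response(DoseResponseSimConfig(noise_sd=0.05, seed=9))[0].to_numpy(),
        ],
        ids=["crispr", "orf", "expression", "barcode", "dose"],
    )
    def test_same_seed_reproduces_data(self, factory):
        assert np.array_equal(factory(), factory())

    def test_chip_reads_deterministic(self):
        g1, r1, _ = simulate_chip_reads(ChipSimConfig(n_genes=20, seed=2))
        g2, r2, _ = simulate_chip_reads(ChipSimConfig(n_genes=20, seed=2))
        pd.testing.assert_frame_equal(r1.records, r2.records)


class TestCrisprScreen:
    def test_truth_ids_exist_in_table(self):
        table, truth = simulate_crispr_screen(SMALL_CRISPR)
        genes = {m[0] for m in table.feature_meta.values()}
        assert truth.essential_genes <= genes
        assert truth.pan_essential_anchor <= truth.essential_genes
        assert truth.unexpressed_genes.isdisjoint(truth.essential_genes)

    def test_control_guides_carry_no_planted_effect(self):
        # mean control LFC ~ 0 up to Monte Carlo error plus the known
        # composition bias from competitive renormalization of the final
        # pool (~ -log2 of surviving abundance mass, < 0.11 at the defaults).
        cfg = CrisprSimConfig(n_genes=1000, n_control_guides=1000, seed=21)
        table, _ = simulate_crispr_screen(cfg)
        lfc = compute_guide_lfc(
            table, ["FINAL_1", "FINAL_2", "FINAL_3"], ["ETP_1", "ETP_2", "ETP_3"]
        )
        controls = [g for g, m in table.feature_meta.items() if m[1]]
        assert abs(lfc[controls].mean()) < 0.2

    def test_planted_depletion_effect_recovered(self):
        cfg = CrisprSimConfig(n_genes=1000, seed=31)
        table, truth = simulate_crispr_screen(cfg)
        lfc = compute_guide_lfc(
            table, ["FINAL_1", "FINAL_2", "FINAL_3"], ["ETP_1", "ETP_2", "ETP_3"]
        )
        scores = aggregate_gene_scores(lfc, table.feature_meta)
        ess = scores[sorted(truth.essential_genes)].mean()
        non = scores[sorted(set(truth.gene_universe) - truth.essential_genes)].mean()
        assert ess - non == pytest.approx(cfg.essential_effect, abs=0.12)

    def test_oversized_library_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_crispr_screen(CrisprSimConfig(n_genes=10_000_000))


class TestOrfScreen:
    def test_planted_rescue_orfs_rank_top_by_drug_lfc(self):
        table, truth = simulate_orf_screen(OrfSimConfig(n_orfs=500, seed=13))
        lfc = compute_orf_lfc(table, ["ETP_1", "ETP_2"], ["JQ1_1", "JQ1_2"]).mean_lfc
        ranks = lfc.rank(ascending=False)
        planted = ranks[sorted(truth.rescue_orfs)].median()
        others = ranks[~ranks.index.isin(truth.rescue_orfs)].median()
        assert planted < others

    def test_cross_arm_r2_approaches_one_without_noise(self):
        cfg = OrfSimConfig(
            n_orfs=300, dispersion=0.0, arm_noise_sd=0.0, drift_sd=0.5,
            mean_reads_per_orf=20_000, seed=17,
        )
        table, _ = simulate_orf_screen(cfg)
        jq1 = compute_orf_lfc(table, ["ETP_1", "ETP_2"], ["JQ1_1", "JQ1_2"]).mean_lfc
        ibet = compute_orf_lfc(table, ["ETP_1", "ETP_2"], ["IBET151_1", "IBET151_2"]).mean_lfc
        assert concordance(jq1, ibet).r_squared > 0.98

    def test_r2_increases_with_effect_to_noise_ratio(self):
        def r2(noise):
            cfg = OrfSimConfig(n_orfs=300, arm_noise_sd=noise, seed=19)
            table, _ = simulate_orf_screen(cfg)
            a = compute_orf_lfc(table, ["ETP_1", "ETP_2"], ["JQ1_1", "JQ1_2"]).mean_lfc
            b = compute_orf_lfc(table, ["ETP_1", "ETP_2"], ["IBET151_1", "IBET151_2"]).mean_lfc
            return concordance(a, b).r_squared

        assert r2(0.05) > r2(1.5)


class TestExpression:
    def test_null_config_calibrated_to_alpha(self):
        from betimed.markers import MarkerConfig, run_marker_selection

        matrix, _ = simulate_expression(
            ExpressionSimConfig(n_genes=400, fraction_suppressed=0.0, seed=23)
        )
        labels = [c.startswith("vehicle") for c in matrix.columns]
        stats = run_marker_selection(matrix, labels, MarkerConfig(seed=23))
        rate = (stats["p"] < 0.05).mean()
        assert 0.02 < rate < 0.08

    def test_unexpressed_genes_sit_below_cutoff_and_are_never_suppressed(self):
        unexpr = {"G00001", "G00002"}
        matrix, truth = simulate_expression(
            ExpressionSimConfig(n_genes=50, seed=3), unexpressed_genes=unexpr
        )
        assert truth.suppressed_genes.isdisjoint(unexpr)
        assert (matrix.loc[sorted(unexpr)].mean(axis=1) < 0.2).all()


class TestBarcodes:
    def test_all_tolerant_all_survive_and_share(self):
        cfg = BarcodeSimConfig(n_barcodes=500, fraction_tolerant=1.0,
                               kill_probability=1.0, seed=5)
        table, truth = simulate_barcode_experiment(cfg)
        from betimed.barcodes import filter_etp, sharing_profile

        eligible = filter_etp(table, "ETP")
        summary = sharing_profile(table, eligible,
                                  [f"JQ1_{i}" for i in range(1, 9)],
                                  [f"DMSO_{i}" for i in range(1, 9)])
        assert summary.surviving_percent == pytest.approx(100.0)
        assert summary.shared_across_all_percent == pytest.approx(100.0, abs=1.0)

    def test_no_tolerant_full_kill_nothing_survives(self):
        cfg = BarcodeSimConfig(n_barcodes=500, fraction_tolerant=0.0,
                               kill_probability=1.0, seed=5)
        table, _ = simulate_barcode_experiment(cfg)
        treated = [f"JQ1_{i}" for i in range(1, 9)]
        assert table.to_frame()[treated].to_numpy().sum() == 0

    def test_sharing_matches_closed_form_expectation(self):
        t, k, r = 0.3, 0.6, 4
        cfg = BarcodeSimConfig(n_barcodes=20_000, n_replicates=r, fraction_tolerant=t,
                               kill_probability=k, seed=29)
        table, _ = simulate_barcode_experiment(cfg)
        from betimed.barcodes import filter_etp, sharing_profile

        eligible = filter_etp(table, "ETP")
        summary = sharing_profile(table, eligible,
                                  [f"JQ1_{i}" for i in range(1, r + 1)],
                                  [f"DMSO_{i}" for i in range(1, r + 1)])
        s = 1 - k
        surv = t + (1 - t) * (1 - k**r)
        shared = (t + (1 - t) * s**r) / surv
        assert summary.shared_across_all_percent == pytest.approx(100 * shared, abs=3.0)
        assert summary.surviving_percent == pytest.approx(100 * surv, abs=3.0)


class TestDoseResponse:
    def test_zero_synergy_zero_noise_gives_zero_excess_everywhere(self):
        matrix, _ = simulate_dose_response(DoseResponseSimConfig())
        result = bliss_excess(DoseMatrix(matrix))
        assert np.allclose(result.excess.to_numpy(), 0.0, atol=1e-12)

    def test_planted_excess_recovered_at_unclipped_well(self):
        noise = 0.02
        cfg = DoseResponseSimConfig(
            doses_a=(0.0, 0.25), doses_b=(0.0, 0.25),
            synergy_excess=0.15, noise_sd=noise, seed=41,
        )
        matrix, truth = simulate_dose_response(cfg)
        result = bliss_excess(DoseMatrix(matrix))
        # combo well far from the clip boundary: planted excess within 2 sd
        # of the three noisy wells feeding the estimate
        assert result.excess.iloc[1, 1] == pytest.approx(0.15, abs=2 * noise * np.sqrt(3))


class TestStudyScenario:
    def test_truth_triple_intersection_is_exactly_the_mediators(self):
        data = simulate_study(StudyConfig(seed=2))
        t = data.truth
        assert t.suppressed_genes & t.essential_genes & t.rescue_genes == t.mediators
        assert len(t.mediators) == 8

    def test_shared_gene_universe_across_assays(self):
        data = simulate_study(StudyConfig(n_genes=300, seed=2))
        crispr_genes = {m[0] for m in data.crispr_counts.feature_meta.values()} - {"NONTARGETING"}
        orf_genes = {m[0] for m in data.orf_counts.feature_meta.values()}
        assert crispr_genes == orf_genes == set(data.expression.index)
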