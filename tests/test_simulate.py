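"""Planted-truth simulator: determinism, zero-noise arithmetic, closed loops."""

from __future__ import annotations

import numpy as np
import pytest

from polysel.contrasts import Thresholds, summarize_contrast
from polysel.gene_sets import GeneSetLabel, assemble_gene_sets
from polysel.seq_features import KozakCategory, UorfMode, feature_frequency, find_uorfs, kozak_call
from polysel.simulate import (
    GeneTruth,
    PlantedClass,
    SimParams,
    SimTruth,
    evaluate_recovery,
    simulate_signals,
    simulate_transcriptome,
)

from conftest import make_cell


def _manual_truth(planted, direction, wt_fold, params):
    genes = [
        GeneTruth(
            gene_id="G1",
            planted_class=planted,
            direction=direction,
            wt_fold=wt_fold,
            mut_fold=wt_fold**params.mutant_attenuation,
            kozak_category=KozakCategory.STRONG,
            uorf_planted=False,
            n_uorfs_realized=0,
        )
    ]
    return SimTruth(genes=genes, params=params)


class TestSimulateSignals:
    def test_zero_noise_cold_tx_down_matches_printed_arithmetic(self):
        # plant the fold that maps control 59.44 to cold 36.24 exactly
        params = SimParams(n_genes=1, noise_cv=0.0, baseline_logmean=np.log(59.44),
                          baseline_logsd=0.0, seed=1)
        truth = _manual_truth(PlantedClass.COLD_TX, -1, 59.44 / 36.24, params)
        matrix = simulate_signals(truth, params)
        wt_ck = matrix.cell_values(make_cell("WT", "CK", "TOTAL"))
        wt_cold = matrix.cell_values(make_cell("WT", "COLD", "TOTAL"))
        np.testing.assert_allclose(wt_ck, 59.44, rtol=1e-12)
        np.testing.assert_allclose(wt_cold, 36.24, rtol=1e-12)
        (res,) = summarize_contrast(
            matrix, make_cell("WT", "CK", "TOTAL"), make_cell("WT", "COLD", "TOTAL")
        )
        assert round(res.signed_fold, 2) == -1.64
        # mutant response abolished
        mut = matrix.cell_values(make_cell("MUT", "COLD", "TOTAL"))
        np.testing.assert_allclose(mut, 59.44, rtol=1e-12)

    def test_zero_noise_cold_tl_leaves_total_flat(self):
        params = SimParams(n_genes=1, noise_cv=0.0, seed=2)
        truth = _manual_truth(PlantedClass.COLD_TL, +1, 2.0, params)
        matrix = simulate_signals(truth, params)
        (total,) = summarize_contrast(
            matrix, make_cell("WT", "CK", "TOTAL"), make_cell("WT", "COLD", "TOTAL")
        )
        (poly,) = summarize_contrast(
            matrix, make_cell("WT", "CK", "POLY"), make_cell("WT", "COLD", "POLY")
        )
        assert total.ratio == pytest.approx(1.0, rel=1e-12)
        assert poly.ratio == pytest.approx(2.0, rel=1e-12)

    def test_nt_effect_hits_mutant_control_cells_only(self):
        params = SimParams(n_genes=1, noise_cv=0.0, seed=3)
        truth = _manual_truth(PlantedClass.NT_GENOTYPE, +1, 3.0, params)
        matrix = simulate_signals(truth, params)
        base = matrix.cell_values(make_cell("WT", "CK", "TOTAL"))[0, 0]
        assert matrix.cell_values(make_cell("MUT", "CK", "TOTAL"))[0, 0] == pytest.approx(3 * base)
        assert matrix.cell_values(make_cell("MUT", "CK", "POLY"))[0, 0] == pytest.approx(3 * base)
        assert matrix.cell_values(make_cell("MUT", "COLD", "TOTAL"))[0, 0] == pytest.approx(base)

    def test_same_seed_byte_identical(self):
        params = SimParams(n_genes=50, seed=11)
        _, truth_a = simulate_transcriptome(params)
        _, truth_b = simulate_transcriptome(params)
        a = simulate_signals(truth_a, params)
        b = simulate_signals(truth_b, params)
        assert a.values.tobytes() == b.values.tobytes()
        assert [s.sample_id for s in a.samples] == [s.sample_id for s in b.samples]

    def test_noise_cv_controls_spread(self):
        params = SimParams(n_genes=500, noise_cv=0.2, n_reps=8, seed=5)
        _, truth = simulate_transcriptome(params)
        matrix = simulate_signals(truth, params)
        reps = matrix.cell_values(make_cell("WT", "CK", "TOTAL"))
        cv = reps.std(axis=1, ddof=1) / reps.mean(axis=1)
        assert np.median(cv) == pytest.approx(0.2, rel=0.2)


class TestSimulateTranscriptome:
    def test_forced_classes_are_realized(self):
        params = SimParams(n_genes=300, kozak_probs=(1.0, 0.0, 0.0, 0.0), seed=7)
        models, truth = simulate_transcriptome(params)
        assert all(kozak_call(m).category is KozakCategory.STRONG for m in models)
        assert all(t.kozak_category is KozakCategory.STRONG for t in truth.genes)

    def test_truth_consistent_with_emitted_sequences(self):
        params = SimParams(n_genes=200, seed=8)
        models, truth = simulate_transcriptome(params)
        by_gene = truth.by_gene()
        for m in models:
            t = by_gene[m.gene_id]
            assert kozak_call(m).category is t.kozak_category
            assert len(find_uorfs(m.utr5, m.cds, UorfMode.CONTAINED)) == t.n_uorfs_realized
            if t.uorf_planted:
                assert t.n_uorfs_realized >= 1

    def test_no_utr_class_has_empty_utr_and_no_uorf(self):
        params = SimParams(n_genes=300, kozak_probs=(0.0, 0.0, 0.0, 1.0), seed=9)
        models, truth = simulate_transcriptome(params)
        assert all(m.utr5 == "" for m in models)
        assert all(t.n_uorfs_realized == 0 for t in truth.genes)

    def test_uorf_needs_room(self):
        with pytest.raises(ValueError, match="uORF"):
            SimParams(utr_len_mean=6.0, uorf_prob=0.5)

    def test_class_prob_validation(self):
        with pytest.raises(ValueError):
            SimParams(class_probs=(0.5, 0.5, 0.5, 0.0))


class TestClosedLoop:
    def test_zero_noise_exact_recovery(self):
        """With no noise and folds >= 1.6, the full pipeline (significance
        waived) recovers exactly the planted genes that clear the expression
        floor — a deterministic screen under zero noise."""
        params = SimParams(
            n_genes=400,
            class_probs=(0.7, 0.1, 0.1, 0.1),
            effect_range=(1.6, 3.0),
            noise_cv=0.0,
            seed=13,
        )
        _, truth = simulate_transcriptome(params)
        matrix = simulate_signals(truth, params)
        sets, _ = assemble_gene_sets(matrix, Thresholds(), grant_significance=True)

        def expressed(gene, fraction):
            """Both contrast sides of both genotypes clear the sum floor."""
            i = matrix.genes.index(gene)
            ok = True
            for genotype in ("WT", "MUT"):
                ck = matrix.cell_values(make_cell(genotype, "CK", fraction))[i].mean()
                cold = matrix.cell_values(make_cell(genotype, "COLD", fraction))[i].mean()
                ok = ok and (ck + cold > 10.0)
            return ok

        def nt_expressed(gene, fraction):
            i = matrix.genes.index(gene)
            wt = matrix.cell_values(make_cell("WT", "CK", fraction))[i].mean()
            mut = matrix.cell_values(make_cell("MUT", "CK", fraction))[i].mean()
            return wt + mut > 10.0

        expected = truth.expected_sets()
        screens = {
            GeneSetLabel.COLD_DOWN_TX: lambda g: expressed(g, "TOTAL"),
            GeneSetLabel.COLD_UP_TX: lambda g: expressed(g, "TOTAL"),
            GeneSetLabel.COLD_DOWN_TL: lambda g: expressed(g, "POLY"),
            GeneSetLabel.COLD_UP_TL: lambda g: expressed(g, "POLY"),
            GeneSetLabel.NT_UP_TX: lambda g: nt_expressed(g, "TOTAL"),
            GeneSetLabel.NT_DOWN_TX: lambda g: nt_expressed(g, "TOTAL"),
        }
        for label, screen in screens.items():
            want = {g for g in expected[label] if screen(g)}
            assert sets[label] == want, label

    def test_planted_nt_up_recovered_exactly(self):
        params = SimParams(
            n_genes=200,
            class_probs=(0.95, 0.0, 0.0, 0.05),
            effect_range=(2.0, 3.0),
            noise_cv=0.0,
            seed=17,
        )
        _, truth = simulate_transcriptome(params)
        planted_up = {
            t.gene_id for t in truth.genes
            if t.planted_class is PlantedClass.NT_GENOTYPE and t.direction > 0
        }
        matrix = simulate_signals(truth, params)
        sets, _ = assemble_gene_sets(matrix, Thresholds(), grant_significance=True)
        assert sets[GeneSetLabel.NT_UP_TX] == planted_up


def test_evaluate_recovery_edge_cases():
    params = SimParams(n_genes=2, noise_cv=0.0, seed=1)
    truth = SimTruth(
        genes=[
            GeneTruth("G1", PlantedClass.COLD_TL, +1, 2.0, 1.0,
                      KozakCategory.STRONG, False, 0),
            GeneTruth("G2", PlantedClass.NULL, 0, 1.0, 1.0,
                      KozakCategory.WEAK, False, 0),
        ],
        params=params,
    )
    perfect = {GeneSetLabel.COLD_UP_TL: {"G1"}}
    report = evaluate_recovery(truth, perfect)
    assert report["COLD_UP_TL"] == {
        "tp": 1, "fp": 0, "fn": 0, "precision": 1.0, "recall": 1.0
    }
    empty = evaluate_recovery(truth, {})
    assert empty["COLD_UP_TL"]["recall"] == 0.0
    assert empty["COLD_UP_TL"]["precision"] is None


def test_uorf_enrichment_visible_in_frequency_table():
    """A planted uORF enrichment (0.8 vs 0.5) separates responder and
    background uORF percentages by well over 20 points of headroom."""
    base = dict(n_genes=300, kozak_probs=(0.4, 0.4, 0.2, 0.0))
    enriched_params = SimParams(**base, uorf_prob=0.8, seed=23)
    background_params = SimParams(**base, uorf_prob=0.5, seed=29)
    models_e, truth_e = simulate_transcriptome(enriched_params)
    models_b, truth_b = simulate_transcriptome(background_params)
    calls = {m.gene_id + "_e": kozak_call(m) for m in models_e}
    calls.update({m.gene_id + "_b": kozak_call(m) for m in models_b})
    uorfs = {t.gene_id + "_e": t.n_uorfs_realized for t in truth_e.genes}
    uorfs.update({t.gene_id + "_b": t.n_uorfs_realized for t in truth_b.genes})
    responders = {t.gene_id + "_e" for t in truth_e.genes}
    background = {t.gene_id + "_b" for t in truth_b.genes}
    table = feature_frequency(
        {"responders": responders}, calls, uorfs, background
    )
    diff = table.rows["responders"]["uorf_pct"] - table.rows["total_genes"]["uorf_pct"]
    assert diff >= 20.0
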