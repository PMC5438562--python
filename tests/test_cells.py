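"""Knee detection, cell selection, filters and per-cell QC."""

import math

import numpy as np
import pandas as pd
import pytest

import dropkit as dk

from conftest import _int_to_barcode, random_dge


def step_totals(n_cells=100, cell_reads=1000, n_ambient=1000, ambient_reads=1):
    barcodes = [_int_to_barcode(i) for i in range(n_cells + n_ambient)]
    values = [cell_reads] * n_cells + [ambient_reads] * n_ambient
    return pd.Series(values, index=barcodes)


class TestFindKnee:
    def test_exact_step_distribution_knee_at_cell_count(self):
        table = dk.barcode_rank(step_totals())
        knee = dk.find_knee(table)
        assert knee.n_cells == 100
        assert knee.confidence_flag == "sharp"

    def test_straight_line_curve_is_weak(self):
        table = dk.barcode_rank(step_totals(n_cells=0, n_ambient=500, ambient_reads=7))
        knee = dk.find_knee(table)
        assert knee.confidence_flag == "weak"

    def test_requires_three_barcodes(self):
        table = dk.barcode_rank(pd.Series({"A" * 12: 5, "C" * 12: 3}))
        with pytest.raises(ValueError):
            dk.find_knee(table)

    def test_recovers_simulated_cell_number_across_seeds(self):
        hits = 0
        for seed in range(20):
            params = dk.SimParams(
                n_cells=100, n_ambient_barcodes=2000,
                library_size_log_mean=math.log(2000), library_size_log_sd=0.4,
                ambient_reads_mean=40.0, reads_per_umi_mean=3.0, seed=seed,
            )
            molecules, _ = dk.simulate_molecules(params)
            knee = dk.find_knee(dk.barcode_rank(dk.read_totals(molecules)))
            hits += 90 <= knee.n_cells <= 110
        assert hits >= 18


class TestSelectCells:
    def test_selecting_all_barcodes_is_identity(self, small_dge):
        assert dk.select_cells(small_dge, small_dge.n_cells).equals(small_dge)

    def test_selecting_one_keeps_highest_total(self, small_dge):
        top = dk.select_cells(small_dge, 1)
        totals = small_dge.umis_per_cell()
        assert list(top.cell_barcodes) == [totals.idxmax()]

    def test_rejects_nonpositive_or_oversized_n(self, small_dge):
        with pytest.raises(ValueError):
            dk.select_cells(small_dge, 0)
        with pytest.raises(ValueError):
            dk.select_cells(small_dge, small_dge.n_cells + 1)

    def test_selected_set_overlaps_true_cells_on_simulated_run(self):
        params = dk.SimParams(
            n_cells=100, n_ambient_barcodes=2000,
            library_size_log_mean=math.log(2000), library_size_log_sd=0.4,
            ambient_reads_mean=40.0, reads_per_umi_mean=3.0, seed=42,
        )
        molecules, truth = dk.simulate_molecules(params)
        dge = dk.count_umis(molecules, assume_valid=True)
        totals = dk.read_totals(molecules)
        selected = dk.select_cells(dge, 100, read_totals=totals)
        true_cells = set(truth.cell_barcodes)
        picked = set(selected.cell_barcodes)
        jaccard = len(picked & true_cells) / len(picked | true_cells)
        assert jaccard >= 0.9


class TestFilters:
    def test_min_umis_is_strictly_fewer_than(self):
        counts = pd.DataFrame(
            [[3499, 3500, 9000]],
            index=["g1"],
            columns=[_int_to_barcode(i) for i in range(3)],
        )
        filtered = dk.filter_min_umis(dk.DgeMatrix(counts), 3500)
        assert filtered.n_cells == 2

    def test_zero_thresholds_are_identity(self, small_dge):
        assert dk.filter_min_umis(small_dge, 0).equals(small_dge)
        assert dk.filter_genes_min_count(small_dge, 0).equals(small_dge)

    @pytest.mark.parametrize("threshold", [3500, 1000, 300, 17])
    def test_cell_filter_matches_brute_force_oracle(self, threshold):
        rng = np.random.default_rng(threshold)
        dge = random_dge(rng, 100, 100, max_count=80)
        kept = dk.filter_min_umis(dge, threshold)
        oracle = [b for b in dge.cell_barcodes
                  if sum(dge.counts[b]) >= threshold]
        assert list(kept.cell_barcodes) == oracle

    @pytest.mark.parametrize("threshold", [1, 5, 40])
    def test_gene_filter_matches_brute_force_oracle(self, threshold):
        rng = np.random.default_rng(threshold + 100)
        dge = random_dge(rng, 100, 100)
        kept = dk.filter_genes_min_count(dge, threshold)
        oracle = [g for g in dge.gene_ids
                  if sum(dge.counts.loc[g]) >= threshold]
        assert list(kept.gene_ids) == oracle

    def test_filters_are_idempotent(self, small_dge):
        once = dk.filter_min_umis(small_dge, 90)
        assert dk.filter_min_umis(once, 90).equals(once)
        once_g = dk.filter_genes_min_count(small_dge, 30)
        assert dk.filter_genes_min_count(once_g, 30).equals(once_g)

    def test_cell_level_filters_commute(self):
        # cell totals do not depend on other cells, so cell filters commute
        rng = np.random.default_rng(0)
        dge = random_dge(rng, 50, 50)
        a = dk.filter_min_umis(dk.keep_best_cells(dge, 30), 20)
        b_kept = dk.filter_min_umis(dge, 20)
        b = dk.keep_best_cells(b_kept, min(30, b_kept.n_cells))
        if a.n_cells == b.n_cells:
            assert a.equals(b)

    def test_keep_best_cells_ties_resolve_lexicographically(self):
        counts = pd.DataFrame(
            [[5, 5, 5]], index=["g1"],
            columns=["G" * 12, "A" * 12, "C" * 12],
        )
        best = dk.keep_best_cells(dk.DgeMatrix(counts), 2)
        assert set(best.cell_barcodes) == {"A" * 12, "C" * 12}

    def test_keep_best_cells_matches_sort_oracle(self):
        rng = np.random.default_rng(9)
        dge = random_dge(rng, 30, 40)
        best = dk.keep_best_cells(dge, 10)
        oracle = sorted(
            dge.cell_barcodes,
            key=lambda b: (-dge.counts[b].sum(), b),
        )[:10]
        assert set(best.cell_barcodes) == set(oracle)


class TestCellQc:
    def test_non_mito_percent_formula(self, annotation):
        counts = pd.DataFrame(
            {"A" * 12: [90, 0, 10, 0, 0, 0]},
            index=["hg_A", "hg_B", "hg_MT1", "mm_A", "mm_B", "mm_MT1"],
        )
        report = dk.cell_qc(dk.DgeMatrix(counts), annotation)
        assert report.per_cell["non_mito_percent"].iloc[0] == 90.0

    def test_cell_without_mito_umis_scores_100(self, annotation):
        counts = pd.DataFrame(
            {"A" * 12: [50, 50, 0, 0, 0, 0]},
            index=["hg_A", "hg_B", "hg_MT1", "mm_A", "mm_B", "mm_MT1"],
        )
        report = dk.cell_qc(dk.DgeMatrix(counts), annotation)
        assert report.per_cell["non_mito_percent"].iloc[0] == 100.0

    def test_mito_and_non_mito_partition_total_exactly(self, small_dge, annotation):
        report = dk.cell_qc(small_dge, annotation)
        per_cell = report.per_cell
        non_mito = per_cell["total_umis"] - per_cell["mito_umis"]
        reconstructed = 100.0 * non_mito / per_cell["total_umis"]
        assert np.allclose(per_cell["non_mito_percent"], reconstructed)
        assert (per_cell["mito_umis"] + non_mito == per_cell["total_umis"]).all()

    def test_unannotated_gene_rejected_by_name(self, annotation):
        counts = pd.DataFrame({"A" * 12: [1]}, index=["mystery_gene"])
        with pytest.raises(KeyError, match="mystery_gene"):
            dk.cell_qc(dk.DgeMatrix(counts), annotation)

    def test_zero_umi_cells_get_nan_and_are_excluded_from_medians(self, annotation):
        counts = pd.DataFrame(
            {"A" * 12: [10, 0, 0, 0, 0, 0], "C" * 12: [0] * 6},
            index=["hg_A", "hg_B", "hg_MT1", "mm_A", "mm_B", "mm_MT1"],
        )
        report = dk.cell_qc(dk.DgeMatrix(counts), annotation)
        assert np.isnan(report.per_cell["non_mito_percent"].iloc[1])
        assert report.summary["median_umis"] == 10
        assert report.summary["n_zero_umi_cells"] == 1

    def test_simulated_mito_fraction_reflected_in_median(self):
        medians = []
        for seed in range(10):
            params = dk.SimParams(
                n_cells=60, n_ambient_barcodes=0, n_genes_per_species=300,
                library_size_log_mean=math.log(1000), mito_gene_fraction=0.1,
                mito_expression_fraction=0.10, seed=seed,
            )
            molecules, _ = dk.simulate_molecules(params)
            dge = dk.count_umis(molecules, assume_valid=True)
            report = dk.cell_qc(dge, dk.simulate_annotation(params))
            medians.append(report.summary["median_non_mito_percent"])
        assert abs(np.mean(medians) - 90.0) < 1.0


class TestNucleusFlag:
    def test_zero_threshold_flags_nothing(self, small_dge, annotation):
        report = dk.cell_qc(small_dge, annotation)
        assert dk.flag_low_mito_cells(report, 0.0) == set()

    def test_cell_without_mito_expression_is_flagged(self, annotation):
        counts = pd.DataFrame(
            {"A" * 12: [100, 0, 0, 0, 0, 0]},
            index=["hg_A", "hg_B", "hg_MT1", "mm_A", "mm_B", "mm_MT1"],
        )
        report = dk.cell_qc(dk.DgeMatrix(counts), annotation)
        assert dk.flag_low_mito_cells(report, 1.0) == {"A" * 12}

    def test_recovers_simulated_nucleus_subpopulation(self):
        # nuclei emulated by a zero-mito sister run merged with normal cells
        params_nuc = dk.SimParams(
            n_cells=40, n_ambient_barcodes=0, n_genes_per_species=300,
            library_size_log_mean=math.log(800), mito_expression_fraction=0.0,
            mito_gene_fraction=0.1, seed=21,
        )
        params_cells = dk.SimParams(
            n_cells=40, n_ambient_barcodes=0, n_genes_per_species=300,
            library_size_log_mean=math.log(800), mito_expression_fraction=0.10,
            mito_gene_fraction=0.1, seed=22,
        )
        mol_nuc, truth_nuc = dk.simulate_molecules(params_nuc)
        mol_cells, _ = dk.simulate_molecules(params_cells)
        merged = pd.concat(
            [mol_nuc.astype({"barcode": str, "gene": str}),
             mol_cells.astype({"barcode": str, "gene": str})],
            ignore_index=True,
        )
        dge = dk.count_umis(merged, assume_valid=True)
        report = dk.cell_qc(dge, dk.simulate_annotation(params_nuc))
        flagged = dk.flag_low_mito_cells(report, 1.0)
        nuclei = set(truth_nuc.cell_barcodes)
        recall = len(flagged & nuclei) / len(nuclei)
        assert recall >= 0.95
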