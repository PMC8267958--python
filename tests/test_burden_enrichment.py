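"""Resampling null, p-total, chi-squared follow-up, end-to-end analysis."""

import itertools
import json
import math

import numpy as np
import pytest

from tlsburden import (
    GeneSet,
    build_matrix,
    chi_squared_vs_random,
    exhaustive_null,
    p_total,
    resample_null,
    run_cancer_type_analysis,
    write_maf,
)
from tlsburden.burden_enrichment import NullDistribution
from tlsburden.synthetic_data import CohortSimParams, simulate_cohort


class TestResampleNull:
    def test_saturated_matrix_counts_equal_n_samples(self, toy_matrix_factory):
        m = toy_matrix_factory(10, 7, 1.1, seed=0)  # density > 1: all cells true
        null = resample_null(m, set_size=3, n_iterations=50, seed=1)
        assert np.all(null.counts == 7)
        assert null.average == 7.0

    def test_set_size_equal_universe_has_no_sampling_freedom(self, toy_matrix_factory):
        m = toy_matrix_factory(6, 9, 0.3, seed=2)
        full_count = int(m.incidence.any(axis=0).sum())
        null = resample_null(m, set_size=6, n_iterations=20, seed=3)
        assert np.all(null.counts == full_count)

    def test_sampled_average_within_three_sigma_of_exhaustive_mean(
        self, toy_matrix_factory
    ):
        m = toy_matrix_factory(8, 6, 0.25, seed=4)
        exact = exhaustive_null(m, set_size=2)  # C(8,2) = 28 sets
        n_iter = 2000
        sampled = resample_null(m, set_size=2, n_iterations=n_iter, seed=5)
        sigma = exact.counts.std(ddof=0) / math.sqrt(n_iter)
        assert abs(sampled.average - exact.average) <= 3 * sigma

    def test_identical_seed_identical_counts(self, toy_matrix_factory):
        m = toy_matrix_factory(30, 12, 0.15, seed=6)
        a = resample_null(m, 5, 200, seed=77)
        b = resample_null(m, 5, 200, seed=77)
        assert np.array_equal(a.counts, b.counts)

    def test_exclude_removes_query_genes_from_universe(self, toy_matrix_factory):
        m = toy_matrix_factory(5, 4, 1.1, seed=0)
        exclude = GeneSet("q", frozenset(["G0", "G1"]))
        with pytest.raises(ValueError, match="universe"):
            resample_null(m, set_size=4, n_iterations=5, seed=1, exclude=exclude)

    def test_universe_smaller_than_set_size_is_an_error(self, toy_matrix_factory):
        m = toy_matrix_factory(3, 4, 0.5, seed=1)
        with pytest.raises(ValueError):
            resample_null(m, set_size=4, n_iterations=10, seed=0)


class TestExhaustiveNull:
    def test_universe_three_choose_three_is_one_count(self, toy_matrix_factory):
        m = toy_matrix_factory(3, 5, 0.4, seed=7)
        null = exhaustive_null(m, set_size=3)
        assert len(null.counts) == 1

    def test_four_choose_two_is_six_counts(self, toy_matrix_factory):
        m = toy_matrix_factory(4, 5, 0.4, seed=8)
        null = exhaustive_null(m, set_size=2)
        assert len(null.counts) == 6

    def test_matches_second_independent_enumeration(self, toy_matrix_factory):
        m = toy_matrix_factory(7, 6, 0.3, seed=9)
        null = exhaustive_null(m, set_size=3)
        # independent enumeration over python sets of sample ids
        mutated = {
            g: {m.samples[j] for j in range(m.n_samples) if m.incidence[i, j]}
            for i, g in enumerate(m.genes)
        }
        expected = sorted(
            len(set().union(*(mutated[g] for g in combo)))
            for combo in itertools.combinations(m.genes, 3)
        )
        assert sorted(null.counts.tolist()) == expected

    def test_combinatorial_cap(self, toy_matrix_factory):
        m = toy_matrix_factory(30, 4, 0.3, seed=10)
        with pytest.raises(ValueError, match="cap"):
            exhaustive_null(m, set_size=15, cap=1000)


class TestPTotal:
    def test_observed_zero_is_one(self):
        null = NullDistribution(np.array([0, 1, 5]), 3, 2, seed=None)
        assert p_total(null, 0) == 1.0

    def test_observed_above_max_is_zero(self):
        null = NullDistribution(np.array([0, 1, 5]), 3, 2, seed=None)
        assert p_total(null, 6) == 0.0

    def test_exhaustive_oracle_by_hand_enumeration(self, toy_matrix_factory):
        m = toy_matrix_factory(6, 5, 0.35, seed=11)
        null = exhaustive_null(m, set_size=2)  # C(6,2) = 15
        counts = sorted(null.counts.tolist())
        for observed in range(m.n_samples + 1):
            expected = sum(1 for c in counts if c >= observed) / len(counts)
            assert p_total(null, observed) == expected

    def test_monotone_non_increasing_in_observed(self, toy_matrix_factory):
        m = toy_matrix_factory(10, 8, 0.3, seed=12)
        null = resample_null(m, 3, 500, seed=13)
        values = [p_total(null, k) for k in range(m.n_samples + 2)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestChiSquared:
    def test_identical_groups_statistic_zero_p_one(self):
        res = chi_squared_vs_random(10, 100, 10.0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert not res.degenerate

    def test_row_swap_symmetry(self):
        a = chi_squared_vs_random(30, 200, 12.0)
        table_swapped = np.array([a.table[1], a.table[0]])
        from scipy.stats import chi2_contingency

        stat, p, _, _ = chi2_contingency(table_swapped, correction=False)
        assert a.statistic == pytest.approx(stat)
        assert a.p_value == pytest.approx(p)

    def test_zero_margin_is_degenerate(self):
        res = chi_squared_vs_random(0, 50, 0.2)  # rounds to 0: zero column margin
        assert res.degenerate
        assert res.p_value == 1.0

    def test_average_rounds_half_up(self):
        res = chi_squared_vs_random(10, 100, 4.5)
        assert res.table[1, 0] == 5

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_vs_random(11, 10, 3.0)
        with pytest.raises(ValueError):
            chi_squared_vs_random(5, 10, 11.0)


class TestEndToEnd:
    @pytest.fixture
    def toy_inputs(self, tmp_path):
        # two overlapping caller files + a 3-gene query set, hand-checkable
        from .test_maf_io import make_record

        caller_a = [
            make_record(gene="TP53", sample="S1", start=10, caller="muse"),
            make_record(gene="KRAS", sample="S2", start=20, caller="muse"),
            make_record(gene="EGFR", sample="S3", start=30, caller="muse"),
            make_record(gene="AAA1", sample="S4", start=40, caller="muse"),
            make_record(gene="BBB1", sample="S5", start=50, caller="muse"),
        ]
        caller_b = [
            make_record(gene="TP53", sample="S1", start=10, caller="mutect2"),  # dup
            make_record(gene="CCC1", sample="S2", start=60, caller="mutect2"),
        ]
        path_a, path_b = tmp_path / "a.maf", tmp_path / "b.maf"
        write_maf(caller_a, path_a)
        write_maf(caller_b, path_b)
        gene_set = GeneSet("query", frozenset(["TP53", "KRAS", "ZZZ9"]))
        return [path_a, path_b], gene_set

    def test_observed_count_matches_hand_count(self, toy_inputs):
        paths, gene_set = toy_inputs
        report = run_cancer_type_analysis(
            paths, gene_set, cancer_type="TOY", seed=3, set_size=2, n_iterations=100
        )
        # hand count: TP53 mutates S1, KRAS mutates S2, ZZZ9 absent -> 2 samples
        assert report.observed_count == 2
        assert report.n_samples == 5
        assert 0.0 <= report.p_total <= 1.0
        assert report.per_gene_frequencies["ZZZ9"] == 0.0
        assert report.per_gene_frequencies["TP53"] == pytest.approx(1 / 5)
        assert report.provenance["n_records_merged"] == 6  # one cross-caller dup

    def test_same_seed_identical_report(self, toy_inputs):
        paths, gene_set = toy_inputs
        kwargs = dict(cancer_type="TOY", seed=5, set_size=2, n_iterations=200)
        r1 = run_cancer_type_analysis(paths, gene_set, **kwargs)
        r2 = run_cancer_type_analysis(paths, gene_set, **kwargs)
        assert json.dumps(r1.to_dict(), sort_keys=True) == json.dumps(
            r2.to_dict(), sort_keys=True
        )
        assert np.array_equal(r1.null.counts, r2.null.counts)

    def test_planted_enrichment_detected(self, tmp_path):
        planted = GeneSet("planted", frozenset(f"PL{i:02d}" for i in range(14)))
        # generator defaults (the simulator's reference cohort) + planted factor 5
        params = CohortSimParams(enriched_set=planted, enrichment_factor=5.0, seed=42)
        records, _ = simulate_cohort(params)
        path = tmp_path / "cohort.maf"
        write_maf(records, path)
        report = run_cancer_type_analysis(
            [path], planted, cancer_type="SIM", seed=9, n_iterations=1000
        )
        assert report.p_total <= 0.05

    def test_patient_level_truncates_barcodes(self, tmp_path):
        from .test_maf_io import make_record

        records = [
            make_record(gene="TP53", sample="TCGA-AA-0001-01A", start=1),
            make_record(gene="TP53", sample="TCGA-AA-0001-01B", start=1),
            make_record(gene="KRAS", sample="TCGA-AA-0002-01A", start=2),
        ]
        path = tmp_path / "p.maf"
        write_maf(records, path)
        gs = GeneSet("q", frozenset(["TP53"]))
        aliquot = run_cancer_type_analysis([path], gs, seed=0, set_size=1, n_iterations=10)
        patient = run_cancer_type_analysis(
            [path], gs, seed=0, set_size=1, n_iterations=10, patient_level=True
        )
        assert aliquot.n_samples == 3
        assert patient.n_samples == 2
        assert patient.observed_count == 1
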