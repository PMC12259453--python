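import math

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_table
from tcrcyto.repertoire_metrics import (
    aggregate_by_cdr3aa,
    classify_clones,
    fisher_2x2,
    sample_statistics,
    sharing_summary,
    simpson_clonality,
    trbv_usage,
    welch_t,
)


class TestAggregate:
    def test_same_aa_different_clonotypes_summed(self):
        table = make_table("P1_CSF", [("CASSAF", 3), ("CASSAF", 2), ("CASSBF", 1)])
        ledger = aggregate_by_cdr3aa([table])
        counts = ledger.entries.set_index("cdr3_aa")["templates"]
        assert counts["CASSAF"] == 5 and counts["CASSBF"] == 1
        assert ledger.totals.loc[("P1", "CSF"), "n_unique_cdr3aa"] == 2

    def test_non_productive_rows_excluded_by_default(self):
        table = make_table("P1_CSF", [("CASSAF", 3), ("CARRNF", 7, "Out")])
        ledger = aggregate_by_cdr3aa([table])
        assert set(ledger.entries["cdr3_aa"]) == {"CASSAF"}
        # but bookkeeping still sees them
        assert ledger.totals.loc[("P1", "CSF"), "total_templates"] == 10
        assert ledger.totals.loc[("P1", "CSF"), "productive_templates"] == 3

    def test_duplicate_sample_rejected(self):
        t = make_table("P1_CSF", [("CASSAF", 1)])
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_by_cdr3aa([t, make_table("P1_CSF", [("CASSBF", 1)])])

    def test_empty_table_gives_zero_totals(self):
        table = make_table("P1_blood", [])
        ledger = aggregate_by_cdr3aa([table])
        assert len(ledger.entries) == 0
        assert ledger.totals.loc[("P1", "blood"), "total_templates"] == 0

    def test_totals_conserve_productive_template_sums(self, small_cohort):
        ledger = aggregate_by_cdr3aa(small_cohort.tables)
        by_sample = ledger.entries.groupby(["patient", "compartment"])["templates"].sum()
        for key, total in ledger.totals["productive_templates"].items():
            assert by_sample.get(key, 0) == total


class TestTaxonomy:
    def test_worked_example_two_patients(self):
        tables = [
            make_table("P1_CSF", [("X", 1), ("Y", 2)]),
            make_table("P1_blood", [("Y", 3), ("Z", 1)]),
            make_table("P2_blood", [("Z", 5)]),
        ]
        labels = classify_clones(aggregate_by_cdr3aa(tables)).set_index(
            ["cdr3_aa", "patient"])
        assert labels.loc[("Y", "P1"), "sharing"] == "shared"
        assert labels.loc[("X", "P1"), "sharing"] == "unique"
        assert labels.loc[("Z", "P1"), "sharing"] == "unique"
        assert labels.loc[("Z", "P1"), "public"]
        assert labels.loc[("Z", "P2"), "public"]
        assert not labels.loc[("X", "P1"), "public"]

    def test_same_compartment_two_patients_is_public_not_shared(self):
        tables = [make_table("P1_CSF", [("Q", 1)]), make_table("P2_CSF", [("Q", 2)])]
        labels = classify_clones(aggregate_by_cdr3aa(tables))
        assert (labels["sharing"] == "unique").all()
        assert labels["public"].all()


class TestSharing:
    def test_percentage_arithmetic(self):
        blood = [(f"B{i}", 1) for i in range(199)] + [("SHARED", 2)]
        csf = [("SHARED", 1), ("C1", 4)]
        ledger = aggregate_by_cdr3aa([make_table("P1_blood", blood),
                                      make_table("P1_CSF", csf)])
        share = sharing_summary(ledger, {"P1": "MS"})
        row = share.per_patient.loc["P1"]
        assert row["pct_shared_of_blood"] == pytest.approx(0.5)
        assert row["pct_shared_of_csf"] == pytest.approx(50.0)

    def test_no_overlap_is_zero_both_directions(self):
        ledger = aggregate_by_cdr3aa([make_table("P1_blood", [("A", 1)]),
                                      make_table("P1_CSF", [("B", 1)])])
        row = sharing_summary(ledger, {"P1": "MS"}).per_patient.loc["P1"]
        assert row["pct_shared_of_blood"] == 0 and row["pct_shared_of_csf"] == 0

    def test_directional_percentages_share_numerator(self, small_cohort):
        ledger = aggregate_by_cdr3aa(small_cohort.tables)
        groups = small_cohort.metadata.drop_duplicates("patient_id").set_index(
            "patient_id")["group"]
        share = sharing_summary(ledger, groups)
        pp = share.per_patient
        lhs = pp["pct_shared_of_blood"] * pp["n_blood"]
        rhs = pp["pct_shared_of_csf"] * pp["n_csf"]
        np.testing.assert_allclose(lhs, rhs)

    def test_unpaired_patient_excluded_and_recorded(self):
        ledger = aggregate_by_cdr3aa([make_table("P1_blood", [("A", 1)]),
                                      make_table("P1_CSF", [("A", 1)]),
                                      make_table("P2_CSF", [("B", 1)])])
        share = sharing_summary(ledger, {"P1": "MS", "P2": "MS"})
        assert share.excluded == ["P2"]
        assert list(share.per_patient.index) == ["P1"]


class TestClonality:
    @pytest.mark.parametrize("counts,expected", [
        ([10], 1.0),
        ([1, 1, 1, 1], 0.5),                   # uniform over 4 -> 1/sqrt(4)
        ([2, 1, 1], math.sqrt(0.375)),
    ])
    def test_closed_forms(self, counts, expected):
        assert simpson_clonality(counts) == pytest.approx(expected)

    def test_decreases_when_splitting_a_clone(self):
        before = simpson_clonality([4, 2, 2])
        after = simpson_clonality([2, 2, 2, 2])  # split the 4 into 2+2
        assert after < before

    def test_empty_rejected_and_evenness_option(self):
        with pytest.raises(ValueError):
            simpson_clonality([])
        assert simpson_clonality([5], method="evenness") == 1.0
        assert 0 < simpson_clonality([5, 1, 1], method="evenness") < 1


class TestSampleStatistics:
    def test_max_frequency_and_totals(self):
        tables = [make_table("P1_CSF", [("A", 10)]),
                  make_table("P2_CSF", [("A", 5), ("B", 15)]),
                  make_table("C1_CSF", [("A", 2), ("B", 2)]),
                  make_table("C2_CSF", [("A", 9), ("B", 1)])]
        groups = {"P1": "MS", "P2": "MS", "C1": "CTRL", "C2": "CTRL"}
        table, tests = sample_statistics(aggregate_by_cdr3aa(tables), groups)
        t = table.set_index("patient")
        assert t.loc["P1", "max_clone_freq_pct"] == pytest.approx(100.0)
        assert t.loc["P2", "max_clone_freq_pct"] == pytest.approx(75.0)
        assert t.loc["P2", "total_templates"] == 20

    def test_welch_matches_hand_formula(self):
        x, y = [1.0, 2.0, 4.0], [10.0, 12.0]
        rec = welch_t(np.array(x), np.array(y))
        t, df = oracles.welch_statistic(x, y)
        assert rec["t"] == pytest.approx(t)
        assert rec["df"] == pytest.approx(df)


class TestTRBVUsage:
    def test_proportions_sum_to_one(self, small_cohort):
        groups = small_cohort.metadata.drop_duplicates("patient_id").set_index(
            "patient_id")["group"]
        blood = [t for t in small_cohort.tables if t.sample_id.endswith("_blood")]
        usage, _ = trbv_usage(blood, groups)
        np.testing.assert_allclose(usage.sum(axis=1), 1.0, atol=1e-12)

    def test_single_gene_repertoire(self):
        t1 = make_table("P1_blood", [("A", 3, "In", "TRBV9"), ("B", 2, "In", "TRBV9")])
        t2 = make_table("C1_blood", [("A", 3, "In", "TRBV9"), ("B", 2, "In", "TRBV28")])
        usage, _ = trbv_usage([t1, t2], {"P1": "MS", "C1": "CTRL"})
        assert usage.loc["P1_blood", "TRBV9"] == pytest.approx(1.0)
        assert usage.loc["C1_blood", "TRBV9"] == pytest.approx(0.6)


class TestFisher2x2:
    def test_symmetric_table(self):
        or_cmle, p = fisher_2x2([[5, 5], [5, 5]])
        assert or_cmle == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_diagonal_table(self):
        or_cmle, p = fisher_2x2([[2, 0], [0, 2]])
        assert math.isinf(or_cmle)
        assert p == pytest.approx(1 / 3)

    def test_p_matches_rational_enumeration(self, rng):
        for _ in range(40):
            t = rng.integers(0, 13, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            _, p = fisher_2x2(t)
            assert p == pytest.approx(oracles.fisher_p_enumeration(t), rel=1e-9)

    def test_or_matches_conditional_mle_oracle(self, rng):
        for _ in range(20):
            t = rng.integers(1, 10, size=(2, 2))
            or_cmle, _ = fisher_2x2(t)
            assert or_cmle == pytest.approx(oracles.fisher_or_cmle(t), rel=1e-5)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            fisher_2x2([[1, -2], [3, 4]])
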