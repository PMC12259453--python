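import math

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_table
from tcrcyto.io_formats import CytokinePanel
from tcrcyto.repertoire_metrics import aggregate_by_cdr3aa
from tcrcyto.tcr_cytokine import (
    AssociationTable,
    associate,
    clone_proportions,
    kendall_tau_b,
    select_predominant,
    select_public,
    tabulate,
)


class TestSelectPublic:
    def test_occupancy_thresholds(self):
        tables = [make_table("P1_blood", [("A", 1), ("B", 2), ("C", 1)]),
                  make_table("P2_blood", [("B", 5), ("C", 1)]),
                  make_table("P3_blood", [("C", 3)])]
        ledger = aggregate_by_cdr3aa(tables)
        assert select_public(ledger) == ["B", "C"]
        assert select_public(ledger, min_samples=3) == ["C"]

    def test_within_patient_compartments_do_not_count_twice(self):
        tables = [make_table("P1_blood", [("A", 1)]), make_table("P1_CSF", [("A", 2)])]
        assert select_public(aggregate_by_cdr3aa(tables)) == []

    def test_invariant_to_clonotype_split(self):
        whole = [make_table("P1_blood", [("A", 4)]), make_table("P2_blood", [("A", 1)])]
        split = [make_table("P1_blood", [("A", 1), ("A", 3)]),
                 make_table("P2_blood", [("A", 1)])]
        assert (select_public(aggregate_by_cdr3aa(whole))
                == select_public(aggregate_by_cdr3aa(split)))


def _blood_cohort(ms_counts, ctrl_counts, depth=1000):
    """Build blood tables where each patient carries a filler clone bringing
    productive totals to ``depth``."""
    tables, groups = [], {}
    for grp, counts in (("MS", ms_counts), ("CTRL", ctrl_counts)):
        for pid, seqs in counts.items():
            filler = depth - sum(seqs.values())
            rows = [(s, c) for s, c in seqs.items()] + [(f"FILL{pid}", filler)]
            tables.append(make_table(f"{pid}_blood", rows))
            groups[pid] = grp
    return aggregate_by_cdr3aa(tables), pd.Series(groups)


class TestSelectPredominant:
    def test_rule_a_boundary_at_five_ms_patients(self):
        ms5 = {f"M{i}": {"SEQ": 10} for i in range(5)}
        ms4 = {f"M{i}": {"SEQ": 10} for i in range(4)}
        ctrl = {"C1": {"OTHER": 5}, "C2": {"SEQ2": 5, "OTHER": 1}}
        ledger, groups = _blood_cohort(ms5, ctrl)
        got = select_predominant(select_public(ledger), ledger, groups)
        assert "SEQ" in got.sequences
        assert got.table.loc["SEQ", "rule"] == "ms_only_ge5"

        ledger4, groups4 = _blood_cohort(ms4, ctrl)
        got4 = select_predominant(select_public(ledger4), ledger4, groups4)
        assert "SEQ" not in got4.sequences

    def test_rule_b_enrichment_and_log2(self):
        # MS mean proportion 1e-3, control mean 5e-5 -> 20x enriched
        ms = {"M1": {"SEQ": 2}, "M2": {"SEQ": 2}}          # 2/1000 each
        ctrl = {"C1": {"SEQ": 1}, "C2": {}, "C3": {}, "C4": {}}
        ledger, groups = _blood_cohort(ms, ctrl, depth=1000)
        # mean MS = 2e-3, mean ctrl = 1/1000/4 = 2.5e-4 -> 8x: below threshold
        got = select_predominant(select_public(ledger), ledger, groups,
                                 enrichment_fold=10)
        assert "SEQ" not in got.sequences
        got = select_predominant(select_public(ledger), ledger, groups,
                                 enrichment_fold=8, pseudo=1e-12)
        assert got.table.loc["SEQ", "rule"] == "enriched_10x"
        assert got.table.loc["SEQ", "log2_enrichment"] == pytest.approx(3.0, abs=1e-6)

    def test_pseudo_must_be_positive(self):
        ledger, groups = _blood_cohort({"M1": {"A": 1}, "M2": {"A": 1}}, {"C1": {}})
        with pytest.raises(ValueError):
            select_predominant(["A"], ledger, groups, pseudo=0.0)

    def test_clone_proportions_denominator_is_productive_total(self):
        tables = [make_table("P1_blood", [("A", 5), ("B", 5), ("NP", 90, "Out")])]
        ledger = aggregate_by_cdr3aa(tables)
        props = clone_proportions(ledger, ["A"], ["P1"])
        assert props.loc["A", "P1"] == pytest.approx(0.5)


class TestKendallTauB:
    def test_perfect_concordance(self):
        tau, p = kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40])
        assert tau == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)  # only the two extreme permutations

    def test_single_swap_example(self):
        tau, _ = kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4])
        assert tau == pytest.approx(2 / 3)

    def test_constant_vector_undefined(self):
        tau, p = kendall_tau_b([1, 2, 3], [5, 5, 5])
        assert math.isnan(tau) and math.isnan(p)

    def test_matches_pair_counting_oracle_randomized(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 9))
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            tau, _ = kendall_tau_b(x, y)
            assert tau == pytest.approx(oracles.kendall_tau_b_pairs(x, y), abs=1e-12)

    def test_exact_p_agrees_with_scipy_when_tie_free(self, rng):
        from scipy import stats
        for _ in range(10):
            n = int(rng.integers(4, 8))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            _, p = kendall_tau_b(x, y)
            expected = stats.kendalltau(x, y, method="exact").pvalue
            assert p == pytest.approx(expected, rel=1e-9)


def _association_setup(n_ms=12, seed=4):
    rng = np.random.default_rng(seed)
    ms = [f"M{i:02d}" for i in range(n_ms)]
    levels = rng.uniform(10, 100, size=n_ms)
    # LINKED clone counts perfectly rank-aligned with the analyte
    order = np.argsort(np.argsort(levels))
    counts = (order + 1) * 3
    tables = []
    for i, pid in enumerate(ms):
        rows = [("LINKED", int(counts[i])), ("FLAT", 10),
                (f"PRIV{pid}", 500 - int(counts[i]) - 10)]
        tables.append(make_table(f"{pid}_blood", rows))
    ledger = aggregate_by_cdr3aa(tables)
    panel = CytokinePanel(pd.DataFrame({"IL-6": levels, "TNF-a": rng.uniform(1, 5, n_ms)},
                                       index=ms))
    pred_table = pd.DataFrame({
        "n_ms_patients": [n_ms, n_ms], "n_ctrl_patients": [0, 0],
        "mean_prop_ms": [0.01, 0.02], "mean_prop_ctrl": [0.0, 0.0],
        "rule": ["ms_only_ge5", "ms_only_ge5"], "log2_enrichment": [5.0, 5.0],
    }, index=pd.Index(["LINKED", "FLAT"], name="cdr3_aa"))
    from tcrcyto.tcr_cytokine import PredominantSet
    return PredominantSet(pred_table, 1e-9), panel, ledger, ms


class TestAssociate:
    def test_planted_monotone_link_significant_with_correct_sign(self):
        predominant, panel, ledger, ms = _association_setup()
        out = associate(predominant, panel, ledger, ms)
        sig = out.significant().set_index(["cdr3_aa", "analyte"])
        assert ("LINKED", "IL-6") in sig.index
        assert sig.loc[("LINKED", "IL-6"), "direction"] == "+"
        assert sig.loc[("LINKED", "IL-6"), "tau"] == pytest.approx(1.0)

    def test_constant_proportion_sequence_skipped(self):
        predominant, panel, ledger, ms = _association_setup()
        out = associate(predominant, panel, ledger, ms)
        assert any(s == "FLAT" and reason == "constant clone proportion"
                   for s, _, reason in out.skipped)
        assert "FLAT" not in set(out.table["cdr3_aa"])

    def test_direction_always_matches_tau_sign(self):
        predominant, panel, ledger, ms = _association_setup(seed=9)
        table = associate(predominant, panel, ledger, ms).table
        assert ((table["tau"] > 0) == (table["direction"] == "+")).all()


class TestTabulate:
    def _assoc(self, rows):
        table = pd.DataFrame(rows, columns=["cdr3_aa", "analyte", "tau", "raw_p",
                                            "adjusted_p", "significant",
                                            "direction", "category",
                                            "log2_enrichment", "rule", "n"])
        return AssociationTable(table, 0.5, 0.05, [])

    def test_hand_built_tally_over_two_categories(self):
        rows = [
            ("S1", "IP-10", 0.8, 0, 0, True, "+", "chemokine", 1, "r", 10),
            ("S2", "IP-10", -0.7, 0, 0, True, "-", "chemokine", 1, "r", 10),
            ("S3", "MIG", 0.9, 0, 0, True, "+", "chemokine", 1, "r", 10),
            ("S1", "SCF", 0.6, 0, 0, True, "+", "growth factor", 1, "r", 10),
            ("S4", "SCF", 0.4, 0.5, 0.9, False, "+", "growth factor", 1, "r", 10),
        ]
        cmap = {"IP-10": "chemokine", "MIG": "chemokine", "SCF": "growth factor"}
        out = tabulate(self._assoc(rows), cmap)
        assert out["per_analyte"]["IP-10"] == {"positive": 1, "negative": 1}
        assert out["per_category"]["chemokine"] == {"positive": 2, "negative": 1}
        assert (out["total_positive"], out["total_negative"]) == (3, 1)
        assert out["n_significant"] == 4
        assert out["sequences_by_n_cytokines"]["S1"] == 2

    def test_counts_conserved_between_levels(self):
        rows = [(f"S{i}", a, 0.6, 0, 0, True, d, c, 1, "r", 10)
                for i, (a, d, c) in enumerate([
                    ("IP-10", "+", "chemokine"), ("SCF", "-", "growth factor"),
                    ("MIG", "+", "chemokine"), ("HGF", "+", "growth factor")])]
        cmap = {"IP-10": "chemokine", "MIG": "chemokine",
                "SCF": "growth factor", "HGF": "growth factor"}
        out = tabulate(self._assoc(rows), cmap)
        per_analyte = sum(v["positive"] + v["negative"]
                          for v in out["per_analyte"].values())
        per_category = sum(v["positive"] + v["negative"]
                           for v in out["per_category"].values())
        assert per_analyte == per_category == out["n_significant"] == 4

    def test_empty_table_all_zero(self):
        out = tabulate(self._assoc([]))
        assert out["n_significant"] == 0
        assert out["per_analyte"] == {} and out["per_category"] == {}
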