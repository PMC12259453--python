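"""Association of MS-predominant TCR sequences with blood cytokine levels.

Workflow: (1) keep public CDR3.aa sequences (seen in at least two
individuals); (2) among those, select MS-predominant sequences — present in
at least ``min_ms`` MS patients and no controls (rule A), or present in both
groups with a >= ``enrichment_fold`` ratio of mean clone proportions (rule
B); (3) correlate each selected sequence's blood clone proportion with each
blood cytokine across MS patients using Kendall's tau-b, Benjamini-Hochberg
adjusted across all tested pairs; an association is significant when the
adjusted p is below alpha and |tau| exceeds ``tau_min``.

A clone proportion is the sequence's summed productive template count
divided by the sample's productive template total; a sequence absent from a
patient contributes proportion zero (not missing), which is what makes a
rank correlation over the whole MS cohort well defined — tau-b's tie
correction absorbs the resulting zero ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .categories import ANALYTE_CATEGORIES
from .correlation_network import bh_adjust
from .io_formats import CytokinePanel
from .repertoire_metrics import CloneLedger


def select_public(ledger: CloneLedger, min_samples: int = 2) -> list[str]:
    """Sequences present in at least ``min_samples`` distinct individuals."""
    occ = ledger.patient_occupancy()
    return sorted(occ.index[occ >= min_samples])


def clone_proportions(
    ledger: CloneLedger, sequences: list[str], patients: list[str]
) -> pd.DataFrame:
    """Sequences x patients matrix of clone proportions (0 when absent).

    The ledger must be restricted to one compartment so the productive
    totals in the denominator are unambiguous.
    """
    counts = (ledger.entries.groupby(["cdr3_aa", "patient"])["templates"].sum()
              .unstack(fill_value=0)
              .reindex(index=sequences, columns=patients, fill_value=0))
    totals = ledger.totals["productive_templates"].groupby("patient").sum()
    denom = totals.reindex(patients)
    if denom.isna().any() or (denom <= 0).any():
        bad = list(denom.index[denom.isna() | (denom <= 0)])
        raise ValueError(f"no productive templates for patient(s) {bad}")
    return counts / denom


@dataclass
class PredominantSet:
    """MS-predominant sequences with the rule each one fired."""

    table: pd.DataFrame  # cdr3_aa-indexed: n_ms_patients, n_ctrl_patients,
    #                      mean_prop_ms, mean_prop_ctrl, rule, log2_enrichment
    pseudo: float

    @property
    def sequences(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def select_predominant(
    public: list[str],
    ledger: CloneLedger,
    groups: Mapping[str, str] | pd.Series,
    min_ms: int = 5,
    enrichment_fold: float = 10.0,
    pseudo: float | None = None,
    ms_label: str = "MS",
    ctrl_label: str = "CTRL",
) -> PredominantSet:
    """Select MS-predominant sequences from the public set.

    Rule A (takes precedence): occurs in >= ``min_ms`` MS patients and in no
    control.  Rule B: occurs in both groups and the mean MS clone proportion
    is >= ``enrichment_fold`` times the mean control proportion.  The default
    pseudocount for the log2 enrichment is half the smallest nonzero
    proportion observed cohort-wide, so rule-A sequences (control proportion
    exactly zero) still get a finite fold change.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    ms_patients = sorted(groups.index[groups == ms_label])
    ctrl_patients = sorted(groups.index[groups == ctrl_label])
    props = clone_proportions(ledger, public, ms_patients + ctrl_patients)
    if pseudo is None:
        nonzero = props.to_numpy()
        nonzero = nonzero[nonzero > 0]
        pseudo = float(nonzero.min() / 2) if nonzero.size else 1e-9
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")

    ms_props = props[ms_patients]
    ctrl_props = props[ctrl_patients]
    n_ms = (ms_props > 0).sum(axis=1)
    n_ctrl = (ctrl_props > 0).sum(axis=1)
    mean_ms = ms_props.mean(axis=1)
    mean_ctrl = ctrl_props.mean(axis=1)

    rule_a = (n_ms >= min_ms) & (n_ctrl == 0)
    rule_b = (n_ms > 0) & (n_ctrl > 0) & (mean_ms >= enrichment_fold * mean_ctrl)
    keep = rule_a | rule_b
    table = pd.DataFrame({
        "n_ms_patients": n_ms[keep].astype(int),
        "n_ctrl_patients": n_ctrl[keep].astype(int),
        "mean_prop_ms": mean_ms[keep],
        "mean_prop_ctrl": mean_ctrl[keep],
        "rule": np.where(rule_a[keep], "ms_only_ge5", "enriched_10x"),
        "log2_enrichment": np.log2((mean_ms[keep] + pseudo) / (mean_ctrl[keep] + pseudo)),
    })
    table.index.name = "cdr3_aa"
    return PredominantSet(table.sort_index(), float(pseudo))


def kendall_tau_b(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Kendall's tau-b with tie correction.

    p-value: exact by permutation enumeration of the concordance statistic S
    for n <= ``exact_max_n`` (valid under ties), tie-corrected normal
    approximation otherwise.  A constant input vector leaves tau undefined:
    returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("kendall_tau_b needs paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    n = x.size
    if n <= exact_max_n:
        tau = float(stats.kendalltau(x, y).statistic)
        iu, ju = np.triu_indices(n, k=1)
        sx = np.sign(x[iu] - x[ju])
        s_obs = float(np.sum(sx * np.sign(y[iu] - y[ju])))
        perms = np.array(list(permutations(y)))
        s_all = np.sign(perms[:, iu] - perms[:, ju]) @ sx
        p = float(np.mean(np.abs(s_all) >= abs(s_obs) - 1e-9))
        assert perms.shape[0] == factorial(n)
        return tau, p
    res = stats.kendalltau(x, y, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class AssociationTable:
    """(sequence, analyte) Kendall associations with joint BH control."""

    table: pd.DataFrame  # cdr3_aa, analyte, tau, raw_p, adjusted_p,
    #                      significant, direction, category, log2_enrichment, rule, n
    tau_min: float
    alpha: float
    skipped: list[tuple[str, str, str]]

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def associate(
    predominant: PredominantSet,
    panel: CytokinePanel,
    ledger: CloneLedger,
    ms_patients: list[str],
    tau_min: float = 0.5,
    alpha: float = 0.05,
    min_pairs: int = 5,
    bh_scope: str = "global",
) -> AssociationTable:
    """Kendall tau-b between clone proportions and cytokine levels.

    Correlations run across MS patients only (blood compartment); patients
    with a not-detected cytokine value are dropped pairwise.  BH adjustment
    is one family across every tested (sequence, analyte) pair by default
    (``bh_scope="per_analyte"`` adjusts within each cytokine instead).
    """
    props = clone_proportions(ledger, predominant.sequences, ms_patients)
    rows, skipped = [], []
    for seq in predominant.sequences:
        sprops = props.loc[seq]
        if sprops.nunique() == 1:
            skipped.append((seq, "*", "constant clone proportion"))
            continue
        for analyte in panel.values.columns:
            levels = panel.values[analyte].reindex(ms_patients)
            ok = levels.notna()
            if int(ok.sum()) < min_pairs:
                skipped.append((seq, analyte, "insufficient pairs"))
                continue
            x = sprops[ok].to_numpy()
            y = levels[ok].to_numpy()
            tau, p = kendall_tau_b(x, y)
            if np.isnan(tau):
                skipped.append((seq, analyte, "degenerate (constant) vector"))
                continue
            rows.append({"cdr3_aa": seq, "analyte": analyte, "tau": tau,
                         "raw_p": p, "n": int(ok.sum())})
    table = pd.DataFrame(rows, columns=["cdr3_aa", "analyte", "tau", "raw_p", "n"])
    if len(table):
        if bh_scope == "global":
            table["adjusted_p"] = bh_adjust(table["raw_p"].to_numpy())
        elif bh_scope == "per_analyte":
            table["adjusted_p"] = (
                table.groupby("analyte")["raw_p"]
                .transform(lambda s: bh_adjust(s.to_numpy())))
        else:
            raise ValueError(f"unknown bh_scope {bh_scope!r}")
        table["significant"] = (table["adjusted_p"] < alpha) & (table["tau"].abs() > tau_min)
        table["direction"] = np.where(table["tau"] > 0, "+", "-")
        cmap = panel.category_map
        table["category"] = [cmap.get(a, "unknown") for a in table["analyte"]]
        table["log2_enrichment"] = (
            table["cdr3_aa"].map(predominant.table["log2_enrichment"]))
        table["rule"] = table["cdr3_aa"].map(predominant.table["rule"])
    else:
        for col in ["adjusted_p", "significant", "direction", "category",
                    "log2_enrichment", "rule"]:
            table[col] = []
    return AssociationTable(table, tau_min, alpha, skipped)


def tabulate(associations: AssociationTable,
             category_map: Mapping[str, str] | None = None) -> dict:
    """Tally significant associations per analyte and functional category.

    Returns per-analyte and per-category positive/negative counts (category
    rows sum to the grand totals), plus sequences ranked by how many
    cytokines they associate with.
    """
    cmap = ANALYTE_CATEGORIES if category_map is None else category_map
    sig = associations.significant()
    per_analyte: dict[str, dict[str, int]] = {}
    per_category: dict[str, dict[str, int]] = {}
    for row in sig.itertuples(index=False):
        a = per_analyte.setdefault(row.analyte, {"positive": 0, "negative": 0})
        c = per_category.setdefault(cmap.get(row.analyte, "unknown"),
                                    {"positive": 0, "negative": 0})
        key = "positive" if row.direction == "+" else "negative"
        a[key] += 1
        c[key] += 1
    seq_counts = (sig.groupby("cdr3_aa")["analyte"].nunique()
                  .sort_values(ascending=False, kind="stable") if len(sig)
                  else pd.Series(dtype=int))
    return {
        "per_analyte": {k: per_analyte[k] for k in sorted(per_analyte)},
        "per_category": {k: per_category[k] for k in sorted(per_category)},
        "total_positive": int((sig["direction"] == "+").sum()) if len(sig) else 0,
        "total_negative": int((sig["direction"] == "-").sum()) if len(sig) else 0,
        "n_significant": int(len(sig)),
        "n_sequences": int(sig["cdr3_aa"].nunique()) if len(sig) else 0,
        "n_analytes": int(sig["analyte"].nunique()) if len(sig) else 0,
        "sequences_by_n_cytokines": {str(k): int(v) for k, v in seq_counts.items()},
    }
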