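"""Clone accounting and repertoire statistics.

Clones are identified by their CDR3 amino-acid sequence: clonotypes (distinct
nucleotide rearrangements / V-J calls) sharing one CDR3.aa are summed into a
single clone per (patient, compartment).  Taxonomy:

* unique clone  — found in exactly one compartment of a patient;
* shared clone  — found in both CSF and blood of that patient;
* public clone  — found in more than one individual (orthogonal axis).

Sharing percentages are computed on distinct-clone counts, in both
directions (share of blood clones also seen in CSF, and vice versa); the
intersection count is the same, only the denominator changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio

from .io_formats import COMPARTMENTS, RearrangementTable


def split_sample_id(sample_id: str) -> tuple[str, str]:
    """Parse '<patient>_<compartment>' sample ids."""
    patient, _, compartment = sample_id.rpartition("_")
    if not patient or compartment not in COMPARTMENTS:
        raise ValueError(
            f"cannot parse sample id {sample_id!r} as <patient>_<compartment>"
        )
    return patient, compartment


@dataclass
class CloneLedger:
    """Cohort-wide CDR3.aa index.

    ``entries``: long table (cdr3_aa, patient, compartment, templates) of
    productive template sums.  ``totals``: per-sample bookkeeping including
    the non-productive rows that the clone index itself excludes.
    """

    entries: pd.DataFrame
    totals: pd.DataFrame  # index (patient, compartment): total_templates,
    #                       productive_templates, productive_rearrangements,
    #                       n_unique_cdr3aa

    def samples(self) -> list[tuple[str, str]]:
        return list(self.totals.index)

    def patients(self) -> list[str]:
        return sorted({p for p, _ in self.totals.index})

    def restrict(self, patients: Iterable[str] | None = None,
                 compartment: str | None = None) -> "CloneLedger":
        e, t = self.entries, self.totals
        if patients is not None:
            patients = set(patients)
            e = e[e["patient"].isin(patients)]
            t = t[t.index.get_level_values(0).isin(patients)]
        if compartment is not None:
            e = e[e["compartment"] == compartment]
            t = t[t.index.get_level_values(1) == compartment]
        return CloneLedger(e.reset_index(drop=True), t)

    def per_patient_counts(self) -> pd.DataFrame:
        """Clone counts summed over compartments: cdr3_aa x patient."""
        return (self.entries.groupby(["cdr3_aa", "patient"])["templates"].sum()
                .unstack(fill_value=0))

    def patient_occupancy(self) -> pd.Series:
        """Per sequence: number of distinct individuals carrying it."""
        return self.entries.groupby("cdr3_aa")["patient"].nunique()


def aggregate_by_cdr3aa(
    tables: Sequence[RearrangementTable],
    sample_map: Mapping[str, tuple[str, str]] | None = None,
    productive_only: bool = True,
) -> CloneLedger:
    """Sum template counts of identical CDR3.aa within each sample.

    ``sample_map`` maps sample_id -> (patient, compartment); by default the
    id is parsed as ``<patient>_<compartment>``.  Duplicate (patient,
    compartment) pairs are rejected.
    """
    seen: set[tuple[str, str]] = set()
    entry_frames, total_rows = [], []
    for table in tables:
        key = (sample_map[table.sample_id] if sample_map is not None
               else split_sample_id(table.sample_id))
        if key in seen:
            raise ValueError(f"duplicate (patient, compartment) sample {key}")
        seen.add(key)
        prod = table.productive()
        if productive_only:
            rows = prod
        else:
            rows = table.data[table.data["amino_acid"].astype(str).str.len() > 0]
        counts = rows.groupby("amino_acid")["templates"].sum()
        counts = counts[counts > 0]
        entry_frames.append(pd.DataFrame({
            "cdr3_aa": counts.index,
            "patient": key[0],
            "compartment": key[1],
            "templates": counts.to_numpy(dtype=int),
        }))
        total_rows.append({
            "patient": key[0],
            "compartment": key[1],
            "total_templates": int(table.data["templates"].sum()),
            "productive_templates": int(prod["templates"].sum()),
            "productive_rearrangements": int(len(prod)),
            "n_unique_cdr3aa": int(len(counts)),
        })
    entries = (pd.concat(entry_frames, ignore_index=True) if entry_frames
               else pd.DataFrame(columns=["cdr3_aa", "patient", "compartment", "templates"]))
    totals = pd.DataFrame(total_rows).set_index(["patient", "compartment"]) if total_rows \
        else pd.DataFrame(columns=["total_templates", "productive_templates",
                                   "productive_rearrangements", "n_unique_cdr3aa"])
    return CloneLedger(entries, totals)


def classify_clones(ledger: CloneLedger) -> pd.DataFrame:
    """Per (clone, patient) labels: sharing in {unique, shared}, public flag."""
    e = ledger.entries
    per_patient = e.groupby(["cdr3_aa", "patient"])["compartment"].nunique()
    occupancy = ledger.patient_occupancy()
    out = per_patient.rename("n_compartments").reset_index()
    out["sharing"] = np.where(out["n_compartments"] > 1, "shared", "unique")
    out["public"] = out["cdr3_aa"].map(occupancy > 1)
    return out[["cdr3_aa", "patient", "sharing", "public"]]


@dataclass
class SharingSummary:
    """Directional shared-clone percentages per patient plus group tests."""

    per_patient: pd.DataFrame      # patient-indexed: n_blood, n_csf, n_shared,
    #                                pct_shared_of_blood, pct_shared_of_csf, group
    group_means: pd.DataFrame      # group x direction means
    tests: dict[str, dict]         # direction -> Welch test record
    excluded: list[str] = field(default_factory=list)


def welch_t(x: np.ndarray, y: np.ndarray) -> dict:
    """Welch's unequal-variance t-test (two-sided) with Welch–Satterthwaite df."""
    res = stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "df": float(res.df), "n_a": len(x), "n_b": len(y)}


def sharing_summary(
    ledger: CloneLedger,
    groups: Mapping[str, str] | pd.Series,
    group_a: str = "MS",
    group_b: str = "CTRL",
) -> SharingSummary:
    """Shared-clone percentages per patient and Welch tests between groups.

    Patients missing either compartment are excluded and recorded — mirrors
    dropping patients whose blood was unavailable for sequencing.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    e = ledger.entries
    rows, excluded = [], []
    for patient in ledger.patients():
        sub = e[e["patient"] == patient]
        blood = set(sub.loc[sub["compartment"] == "blood", "cdr3_aa"])
        csf = set(sub.loc[sub["compartment"] == "CSF", "cdr3_aa"])
        if not blood or not csf:
            excluded.append(patient)
            continue
        shared = len(blood & csf)
        rows.append({
            "patient": patient,
            "group": groups.get(patient),
            "n_blood": len(blood),
            "n_csf": len(csf),
            "n_shared": shared,
            "pct_shared_of_blood": 100.0 * shared / len(blood),
            "pct_shared_of_csf": 100.0 * shared / len(csf),
        })
    per_patient = pd.DataFrame(rows).set_index("patient") if rows else pd.DataFrame(
        columns=["group", "n_blood", "n_csf", "n_shared",
                 "pct_shared_of_blood", "pct_shared_of_csf"])
    directions = ["pct_shared_of_blood", "pct_shared_of_csf"]
    group_means = per_patient.groupby("group")[directions].mean() if len(per_patient) \
        else pd.DataFrame(columns=directions)
    tests = {}
    for direction in directions:
        x = per_patient.loc[per_patient["group"] == group_a, direction].to_numpy()
        y = per_patient.loc[per_patient["group"] == group_b, direction].to_numpy()
        if len(x) >= 2 and len(y) >= 2:
            tests[direction] = welch_t(x, y)
    return SharingSummary(per_patient, group_means, tests, excluded)


def simpson_clonality(counts, method: str = "root_simpson") -> float:
    """Clonality of one sample from productive clone counts.

    ``root_simpson`` (default, the immunoSEQ Analyzer convention) is
    sqrt(sum p_i^2): 1 for a monoclonal sample, 1/sqrt(N) for N equal clones.
    ``evenness`` is the alternative 1 - H/ln(R) (Shannon-evenness based).
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("empty sample: clonality undefined")
    p = c / c.sum()
    if method == "root_simpson":
        return float(np.sqrt((p ** 2).sum()))
    if method == "evenness":
        if p.size == 1:
            return 1.0
        h = -(p * np.log(p)).sum()
        return float(1.0 - h / np.log(p.size))
    raise ValueError(f"unknown clonality method {method!r}")


def sample_statistics(
    ledger: CloneLedger,
    groups: Mapping[str, str] | pd.Series,
    group_a: str = "MS",
    group_b: str = "CTRL",
) -> tuple[pd.DataFrame, dict]:
    """Per-sample summary statistics plus per-compartment Welch tests.

    "Total T cells" is the total template count (productive + non-productive);
    max clone frequency is the largest productive clone proportion in percent.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    rows = []
    for (patient, compartment), tot in ledger.totals.iterrows():
        counts = ledger.entries.query(
            "patient == @patient and compartment == @compartment")["templates"]
        prod_total = tot["productive_templates"]
        rows.append({
            "patient": patient,
            "compartment": compartment,
            "group": groups.get(patient),
            "total_templates": int(tot["total_templates"]),
            "productive_templates": int(prod_total),
            "productive_rearrangements": int(tot["productive_rearrangements"]),
            "n_unique_cdr3aa": int(tot["n_unique_cdr3aa"]),
            "max_clone_freq_pct": (100.0 * counts.max() / prod_total
                                   if prod_total > 0 and len(counts) else np.nan),
            "clonality": (simpson_clonality(counts) if len(counts) else np.nan),
        })
    table = pd.DataFrame(rows)
    metrics = ["total_templates", "productive_templates",
               "max_clone_freq_pct", "clonality"]
    tests: dict = {}
    for compartment in sorted(table["compartment"].unique()):
        sub = table[table["compartment"] == compartment]
        for metric in metrics:
            x = sub.loc[sub["group"] == group_a, metric].dropna().to_numpy()
            y = sub.loc[sub["group"] == group_b, metric].dropna().to_numpy()
            if len(x) >= 2 and len(y) >= 2:
                tests[(compartment, metric)] = welch_t(x, y)
    return table, tests


def trbv_usage(
    tables: Sequence[RearrangementTable],
    groups: Mapping[str, str] | pd.Series,
    group_a: str = "MS",
    group_b: str = "CTRL",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample TRBV gene usage proportions and per-gene group comparison.

    Proportion = productive templates assigned to the gene / sample
    productive total (rows sum to 1).  Per gene: Mann-Whitney U between the
    two groups with BH adjustment across genes, plus a variability rank by
    cross-sample variance of the usage proportion.
    """
    from .correlation_network import bh_adjust
    from .cytokine_stats import _mann_whitney

    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    usage_rows = {}
    for table in tables:
        prod = table.productive()
        total = prod["templates"].sum()
        if total == 0:
            continue
        usage_rows[table.sample_id] = prod.groupby("v_gene")["templates"].sum() / total
    usage = pd.DataFrame(usage_rows).T.fillna(0.0).sort_index(axis=1)
    usage.index.name = "sample_id"

    sample_groups = pd.Series(
        {sid: groups.get(split_sample_id(sid)[0], groups.get(sid)) for sid in usage.index}
    )
    rows = []
    for gene in usage.columns:
        x = usage.loc[sample_groups == group_a, gene].to_numpy()
        y = usage.loc[sample_groups == group_b, gene].to_numpy()
        if len(x) < 2 or len(y) < 2:
            continue
        stat, p = _mann_whitney(x, y)
        rows.append({"v_gene": gene, "statistic": stat, "raw_p": p,
                     "mean_a": x.mean(), "mean_b": y.mean(),
                     "variance": float(usage[gene].var(ddof=1))})
    comparison = pd.DataFrame(rows).set_index("v_gene") if rows else pd.DataFrame(
        columns=["statistic", "raw_p", "mean_a", "mean_b", "variance"])
    if len(comparison):
        comparison["adjusted_p"] = bh_adjust(comparison["raw_p"].to_numpy())
        comparison["significant"] = comparison["adjusted_p"] < alpha
        comparison["variability_rank"] = (
            comparison["variance"].rank(ascending=False, method="min").astype(int))
    return usage, comparison


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns (conditional-MLE odds ratio, p).  The p-value sums hypergeometric
    point probabilities not exceeding that of the observed table (with the
    customary tiny relative tolerance); the odds ratio is the conditional
    maximum-likelihood estimate, +inf when an off-diagonal zero forces it.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("fisher_2x2 expects a 2x2 table")
    if (arr < 0).any() or not np.all(arr == np.floor(arr)):
        raise ValueError("fisher_2x2 expects non-negative integer counts")
    arr = arr.astype(int)
    p = float(stats.fisher_exact(arr, alternative="two-sided").pvalue)
    or_cmle = float(odds_ratio(arr, kind="conditional").statistic)
    return or_cmle, p
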