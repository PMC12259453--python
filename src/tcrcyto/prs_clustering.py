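"""Potentially relevant sequences (PRS) and their rank-based clustering.

A CDR3.aa sequence from MS cerebrospinal fluid is a PRS if it is (1) among
the top-10 clones by summed count in at least one MS patient's CSF with a
count of at least two, or (2) present in the CSF of at least two different
MS patients.

To separate MS-associated from generally occurring PRS, each individual's
summed clone counts for the PRS set are converted to within-individual ranks
(rank 1 = most abundant; sequences absent from an individual share the tied
bottom rank), k-means with k = 2 partitions the PRS over these rank
profiles, and the cluster with the higher mean occurrence across MS
individuals is labelled MS-associated.  PCA supplies 2-D coordinates for
inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .repertoire_metrics import CloneLedger, welch_t


@dataclass
class PRSSet:
    """PRS table: one row per sequence with criterion flags and sources."""

    table: pd.DataFrame  # cdr3_aa-indexed: top10_csf, multi_patient_csf,
    #                      n_csf_patients, patients (';'-joined)

    @property
    def sequences(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RankMatrix:
    """PRS x individuals rank matrix plus the presence mask behind it."""

    ranks: pd.DataFrame      # rows = PRS, columns = individuals
    presence: pd.DataFrame   # same shape, count > 0
    sample_groups: pd.Series  # individual -> group label (MS / HEALTHY_REF)


@dataclass
class ClusterAssignment:
    """k = 2 partition of the PRS with PCA coordinates and occurrence means."""

    labels: pd.Series        # cdr3_aa -> {"ms_associated", "general"}
    pca_coords: pd.DataFrame  # cdr3_aa x (PC1, PC2)
    explained_variance: np.ndarray
    occurrence: pd.DataFrame  # cdr3_aa x group occurrence (%)
    inertia: float


def identify_prs(
    ms_csf_ledger: CloneLedger,
    top_n: int = 10,
    min_count: int = 2,
    min_patients: int = 2,
) -> PRSSet:
    """Apply both PRS criteria to the MS CSF ledger and return the union.

    Criterion 1 honours ties: every sequence tied with the ``top_n``-th count
    in a patient is included (subject to ``min_count``).
    """
    e = ms_csf_ledger.entries
    crit1: set[str] = set()
    for _, sub in e.groupby("patient"):
        counts = sub.set_index("cdr3_aa")["templates"]
        if len(counts) == 0:
            continue
        order = counts.sort_values(ascending=False, kind="stable")
        if len(order) > top_n:
            cutoff = order.iloc[top_n - 1]
            order = order[order >= cutoff]
        crit1.update(order[order >= min_count].index)
    occupancy = e.groupby("cdr3_aa")["patient"].nunique()
    crit2 = set(occupancy[occupancy >= min_patients].index)
    members = sorted(crit1 | crit2)
    patients_of = e.groupby("cdr3_aa")["patient"].agg(lambda s: ";".join(sorted(set(s))))
    table = pd.DataFrame({
        "top10_csf": [seq in crit1 for seq in members],
        "multi_patient_csf": [seq in crit2 for seq in members],
        "n_csf_patients": [int(occupancy.get(seq, 0)) for seq in members],
        "patients": [patients_of.get(seq, "") for seq in members],
    }, index=pd.Index(members, name="cdr3_aa"))
    return PRSSet(table)


def build_rank_matrix(prs: PRSSet, ledger: CloneLedger,
                      sample_groups: pd.Series) -> RankMatrix:
    """Rank each individual's summed PRS clone counts.

    ``ledger`` spans the comparison individuals (MS plus healthy reference,
    all compartments; counts are summed per individual).  Rank 1 = largest
    count; ties get average ranks; absent sequences (count 0) share the tied
    bottom rank, which keeps every column a valid ranking of the same
    dimension.
    """
    if len(prs) == 0:
        raise ValueError("PRS set is empty")
    counts = ledger.per_patient_counts().reindex(prs.sequences, fill_value=0)
    individuals = [p for p in ledger.patients()]
    counts = counts.reindex(columns=individuals, fill_value=0)
    ranks = pd.DataFrame(
        {ind: rankdata(-counts[ind].to_numpy(), method="average")
         for ind in individuals},
        index=counts.index,
    )
    presence = counts > 0
    return RankMatrix(ranks, presence, sample_groups.reindex(individuals))


def _occurrence(presence: pd.DataFrame, sample_groups: pd.Series) -> pd.DataFrame:
    """Per sequence: percent of each group's individuals carrying it."""
    out = {}
    for group in sample_groups.dropna().unique():
        members = sample_groups.index[sample_groups == group]
        out[group] = 100.0 * presence[members].mean(axis=1)
    return pd.DataFrame(out)


def kmeans_two(
    rank_matrix: RankMatrix,
    seed: int,
    n_init: int = 25,
    ms_group: str = "MS",
) -> ClusterAssignment:
    """Euclidean k-means (k = 2) on rank profiles, seeded and restarted.

    The cluster whose members occur more often across MS individuals is
    labelled ``ms_associated``; the other ``general``.  A degenerate matrix
    (all rows identical) cannot support two clusters and is rejected.
    """
    X = rank_matrix.ranks.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two PRS rows to cluster")
    if np.allclose(X, X[0]):
        raise ValueError(
            "all rank profiles are identical: a two-cluster partition is "
            "meaningless; inspect the PRS counts"
        )
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    occurrence = _occurrence(rank_matrix.presence, rank_matrix.sample_groups)
    ms_occ = occurrence[ms_group]
    means = [ms_occ[raw == c].mean() for c in (0, 1)]
    ms_cluster = int(np.argmax(means))
    labels = pd.Series(
        np.where(raw == ms_cluster, "ms_associated", "general"),
        index=rank_matrix.ranks.index, name="cluster",
    )
    coords, explained = pca_project(rank_matrix.ranks)
    return ClusterAssignment(labels, coords, explained, occurrence,
                             float(km.inertia_))


def pca_project(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered 2-component PCA with deterministic sign convention.

    Each component's sign is fixed by making its largest-magnitude loading
    positive.  Zero-variance input is rejected.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two rows")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance matrix: PCA undefined")
    n_comp = min(2, X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    for k in range(n_comp):
        lead = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, lead] < 0:
            coords[:, k] *= -1
    if n_comp == 1:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    frame = pd.DataFrame(coords[:, :2], index=matrix.index, columns=["PC1", "PC2"])
    return frame, pca.explained_variance_ratio_


def cluster_occurrence_test(
    assignment: ClusterAssignment,
    ms_group: str = "MS",
    ref_group: str = "HEALTHY_REF",
) -> dict:
    """Per-cluster occurrence means in MS vs healthy, Welch-tested over sequences."""
    out: dict = {}
    for cluster in ("ms_associated", "general"):
        seqs = assignment.labels.index[assignment.labels == cluster]
        if len(seqs) == 0:
            out[cluster] = {"n_sequences": 0, "skipped": "empty cluster"}
            continue
        ms = assignment.occurrence.loc[seqs, ms_group].to_numpy()
        ref = assignment.occurrence.loc[seqs, ref_group].to_numpy()
        rec = {
            "n_sequences": int(len(seqs)),
            "mean_occurrence_ms": float(ms.mean()),
            "mean_occurrence_ref": float(ref.mean()),
        }
        if len(seqs) >= 2:
            rec["welch"] = welch_t(ms, ref)
        out[cluster] = rec
    return out
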