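"""Synthetic study generator with known planted structure.

Emulates a paired CSF/blood cohort — MS patients and non-inflammatory
controls with a 48-analyte cytokine panel and immunoSEQ-style TCRβ
rearrangement tables, plus a blood-only "healthy reference" repertoire
cohort — so that every downstream stage can be validated against ground
truth.  What is planted, and how each is recovered:

* group fold changes on cytokines (log-normal concentrations; MS CSF means
  scaled by the configured factor) — recovered by group comparison;
* correlated analyte blocks (equicorrelated multivariate-normal log levels)
  — recovered as connected components of the correlation network;
* clone-size power law (Zipf ranks with log-normal jitter);
* within-patient CSF→blood clone sharing at a configured rate (counts
  re-drawn on the blood side, so recovery estimates are non-trivial);
* cross-patient public clones via a common sequence pool (a patient's CSF
  and blood draws from that pool are disjoint, so within-patient sharing is
  controlled exclusively by the sharing rate);
* MS-enriched CSF sequences that qualify as PRS and occur at different
  rates in MS vs healthy individuals — recovered by rank k-means;
* sequence–cytokine links with a target Kendall tau, planted through a
  Gaussian copula between the analyte's latent level and the clone count.

Determinism: one integer seed drives a PCG64 stream; identical config +
seed reproduce the cohort byte-for-byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .categories import ANALYTE_CATEGORIES
from .io_formats import (
    CytokinePanel,
    RearrangementTable,
    validate_metadata,
    write_cytokines,
    write_metadata,
    write_rearrangements,
)

AA_ALPHABET = "ADEFGHIKLMNPQRSTVWY"  # 19 letters; C reserved for the leading anchor
NT_ALPHABET = "ACGT"

TRBV_GENES = [
    "TRBV2", "TRBV3-1", "TRBV4-1", "TRBV5-1", "TRBV6-1", "TRBV6-5", "TRBV7-2",
    "TRBV7-9", "TRBV9", "TRBV10-3", "TRBV11-2", "TRBV12-3", "TRBV13", "TRBV14",
    "TRBV15", "TRBV18", "TRBV19", "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27",
    "TRBV28", "TRBV29-1", "TRBV30",
]
TRBD_GENES = ["TRBD1", "TRBD2"]
TRBJ_GENES = ["TRBJ1-1", "TRBJ1-2", "TRBJ1-5", "TRBJ2-1", "TRBJ2-2", "TRBJ2-3",
              "TRBJ2-5", "TRBJ2-7"]

#: analytes generated mostly below the detection threshold, emulating the
#: sparse "not detected" pattern of low-abundance cytokines.
SPARSE_ANALYTES = ("IL-3", "IL-5", "IL-7", "b-NGF")


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the emulated study's shape: 24 MS + 9 control
    patients with paired CSF/blood, an 88-individual blood-only healthy
    reference cohort, 48 analytes, two MS-elevated CSF cytokines (2.57- and
    1.91-fold), one four-analyte correlation block at r = 0.9, and planted
    sequence–cytokine links at |tau| = 0.7/0.6.
    """

    n_ms: int = 24
    n_ctrl: int = 9
    n_healthy_ref: int = 88
    n_analytes: int = 48
    clones_per_blood: int = 4000
    clones_per_csf: int = 1000
    zipf_exponent: float = 1.0
    sharing_rate_ms: float = 0.005
    sharing_rate_ctrl: float = 0.001
    planted_fold_changes: dict = field(
        default_factory=lambda: {"MIP-1a": 2.57, "IP-10": 1.91})
    correlation_blocks: list = field(
        default_factory=lambda: [(("IP-10", "MIG", "G-CSF", "IL-9"), 0.9)])
    planted_links: list = field(
        default_factory=lambda: [("PLANT-1", "SCF", 0.7), ("PLANT-2", "TRAIL", -0.6)])
    detection_limit: float = 3.0
    hla_prevalence_ms: float = 0.5
    hla_prevalence_ctrl: float = 0.125
    noise_log2_sd: float = 0.4
    nonproductive_fraction: float = 0.15
    clonotype_split_fraction: float = 0.05
    public_clone_fraction: float = 0.10
    public_pool_size: int = 200_000
    n_ms_enriched_prs: int = 30
    prs_occurrence_ms: float = 0.20
    prs_occurrence_healthy: float = 0.04
    trbv_shift: tuple | None = None  # (gene, factor) applied to the MS group
    seed: int = 0

    def analytes(self) -> list[str]:
        names = list(ANALYTE_CATEGORIES)
        if self.n_analytes > len(names):
            raise ValueError(f"n_analytes must be <= {len(names)}")
        return names[: self.n_analytes]

    def validate(self) -> None:
        for name in ("sharing_rate_ms", "sharing_rate_ctrl", "hla_prevalence_ms",
                     "hla_prevalence_ctrl", "nonproductive_fraction",
                     "clonotype_split_fraction", "public_clone_fraction",
                     "prs_occurrence_ms", "prs_occurrence_healthy"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.clones_per_blood <= 0 or self.clones_per_csf <= 0:
            raise ValueError("clone counts must be positive")
        if self.clones_per_csf > self.clones_per_blood:
            warnings.warn("clones_per_csf exceeds clones_per_blood (unusual)")
        analytes = set(self.analytes())
        for a in self.planted_fold_changes:
            if a not in analytes:
                raise ValueError(f"planted fold-change analyte {a!r} not in panel")
            if self.planted_fold_changes[a] <= 0:
                raise ValueError("fold changes must be positive")
        seen: set[str] = set()
        for block, rho in self.correlation_blocks:
            if not -1 < rho < 1:
                raise ValueError(f"block correlation must be in (-1, 1), got {rho}")
            k = len(block)
            if k < 2:
                raise ValueError(f"correlation block {block} needs >=2 analytes")
            if rho < -1.0 / (k - 1):
                raise ValueError(
                    f"non-PSD correlation block {tuple(block)}: equicorrelation "
                    f"{rho} with {k} analytes is not positive semi-definite")
            if seen & set(block):
                raise ValueError(f"correlation blocks overlap at {seen & set(block)}")
            if set(block) - analytes:
                raise ValueError(f"block analytes {set(block) - analytes} not in panel")
            seen |= set(block)
        for label, analyte, tau in self.planted_links:
            if analyte not in analytes:
                raise ValueError(f"planted link analyte {analyte!r} not in panel")
            if not -1 <= tau <= 1:
                raise ValueError(f"planted tau must be in [-1, 1], got {tau}")

    def ms_patients(self) -> list[str]:
        return [f"MS{i + 1:02d}" for i in range(self.n_ms)]

    def ctrl_patients(self) -> list[str]:
        return [f"CTRL{i + 1:02d}" for i in range(self.n_ctrl)]

    def healthy_patients(self) -> list[str]:
        return [f"HR{i + 1:02d}" for i in range(self.n_healthy_ref)]


@dataclass
class GroundTruth:
    """Planted values echoed from the config plus realized quantities."""

    planted_fold_changes: dict
    realized_fold_changes: dict          # analyte -> realized MS/CTRL ratio (CSF)
    correlation_blocks: list
    realized_block_correlations: dict    # "a|b" -> mean pairwise r (CSF, log2)
    planted_links: list
    planted_link_sequences: dict         # label -> cdr3_aa
    planted_prs_sequences: list
    realized_sharing: dict               # patient -> shared / n_csf
    sharing_rate_ms: float
    sharing_rate_ctrl: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticCohort:
    """Everything one simulated study produces."""

    config: CohortConfig
    panels: dict                      # compartment -> CytokinePanel (masked)
    latent_log2: dict                 # compartment -> unmasked log2 matrix
    tables: list                      # RearrangementTable, one per sample
    metadata: pd.DataFrame
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# sequence encoding


def _encode_ids(ids: np.ndarray, alphabet: str = AA_ALPHABET, width: int = 8) -> np.ndarray:
    """Deterministic integer -> fixed-width string over ``alphabet``."""
    base = len(alphabet)
    letters = np.frombuffer(alphabet.encode(), dtype="S1")
    out = np.empty((len(ids), width), dtype="S1")
    rem = ids.astype(np.int64).copy()
    for k in range(width - 1, -1, -1):
        out[:, k] = letters[rem % base]
        rem //= base
    return out.view(f"S{width}").ravel().astype(str)


_SCRAMBLE = 99999989  # coprime to 19**8, so id -> id*c mod 19**8 is a bijection
#                       (and small enough that id*c stays inside int64)


def _make_cdr3aa(ids: np.ndarray) -> np.ndarray:
    ids = (np.asarray(ids, dtype=np.int64) * _SCRAMBLE) % (19 ** 8)
    body = _encode_ids(ids)
    return np.char.add(np.char.add("CASS", body), "F")


def _random_nt(rng: np.random.Generator, n: int, length: int = 39) -> np.ndarray:
    letters = np.frombuffer(NT_ALPHABET.encode(), dtype="S1")
    arr = letters[rng.integers(0, 4, size=(n, length))]
    return arr.view(f"S{length}").ravel().astype(str)


def _label_to_sequence(label: str) -> str:
    """Deterministic planted-sequence identity from its config label."""
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % (19 ** 8)
    return "CASS" + _encode_ids(np.array([h]))[0] + "QYF"


# ---------------------------------------------------------------------------
# cytokines


def _correlation_matrix(config: CohortConfig) -> np.ndarray:
    analytes = config.analytes()
    idx = {a: i for i, a in enumerate(analytes)}
    C = np.eye(len(analytes))
    for block, rho in config.correlation_blocks:
        ii = [idx[a] for a in block]
        for a in ii:
            for b in ii:
                if a != b:
                    C[a, b] = rho
    eig = np.linalg.eigvalsh(C)
    if eig.min() < -1e-9:
        raise ValueError("correlation specification is not positive semi-definite")
    return C


def generate_cytokines(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[dict, dict, dict]:
    """Generate masked panels and unmasked latent log2 matrices per compartment.

    Returns (panels, latent_log2, realized) where ``realized`` holds the
    realized fold changes and block correlations for the ground truth.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    analytes = config.analytes()
    base_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    baseline = pd.Series(base_rng.uniform(3.5, 8.0, size=len(analytes)), index=analytes)
    limit_log2 = np.log2(config.detection_limit + 1e-300)
    for a in SPARSE_ANALYTES:
        if a in baseline.index and a not in config.planted_fold_changes:
            baseline[a] = limit_log2 - 0.3
    C = _correlation_matrix(config)
    chol = np.linalg.cholesky(C + 1e-12 * np.eye(len(analytes)))

    patients = config.ms_patients() + config.ctrl_patients()
    n_ms = config.n_ms
    panels, latent, realized_fold, realized_blocks = {}, {}, {}, {}
    for compartment in ("CSF", "blood"):
        Z = rng.standard_normal((len(patients), len(analytes))) @ chol.T
        log2v = baseline.to_numpy() + config.noise_log2_sd * Z
        if compartment == "CSF":
            for a, fold in config.planted_fold_changes.items():
                log2v[:n_ms, analytes.index(a)] += np.log2(fold)
        raw = np.power(2.0, log2v)
        frame = pd.DataFrame(raw, index=patients, columns=analytes)
        masked = frame.where(frame >= config.detection_limit)
        panels[compartment] = CytokinePanel(masked)
        latent[compartment] = pd.DataFrame(log2v, index=patients, columns=analytes)
        if compartment == "CSF":
            for a in config.planted_fold_changes:
                ms_mean = frame.iloc[:n_ms][a].mean()
                ct_mean = frame.iloc[n_ms:][a].mean()
                realized_fold[a] = float(ms_mean / ct_mean)
            for block, rho in config.correlation_blocks:
                sub = latent[compartment][list(block)].corr().to_numpy()
                realized_blocks["|".join(block)] = float(
                    sub[np.triu_indices(len(block), 1)].mean())
    realized = {"fold_changes": realized_fold, "block_correlations": realized_blocks}
    return panels, latent, realized


# ---------------------------------------------------------------------------
# repertoires


def _zipf_counts(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Zipf-law clone counts with log-normal jitter, shuffled over clones."""
    ranks = np.arange(1, n + 1, dtype=float)
    scale = 5.0 * n ** exponent
    jitter = np.exp(rng.normal(0.0, 0.3, size=n))
    counts = np.maximum(1, np.round(scale * ranks ** (-exponent) * jitter)).astype(int)
    rng.shuffle(counts)
    return counts


def _sample_genes(rng: np.random.Generator, n: int, v_probs: np.ndarray):
    v = rng.choice(TRBV_GENES, size=n, p=v_probs)
    d = rng.choice(TRBD_GENES, size=n)
    j = rng.choice(TRBJ_GENES, size=n)
    return v, d, j


def _build_table(
    rng: np.random.Generator,
    sample_id: str,
    aa: np.ndarray,
    counts: np.ndarray,
    config: CohortConfig,
    v_probs: np.ndarray,
) -> RearrangementTable:
    """Assemble one rearrangement TSV worth of rows from clone-level data.

    Adds clonotype splits (same CDR3.aa, different nucleotide rearrangement,
    counts partitioned) and non-productive rows on top of the productive
    clone list.
    """
    n = len(aa)
    n_split = int(round(config.clonotype_split_fraction * n))
    split_idx = rng.choice(n, size=n_split, replace=False) if n_split else np.array([], int)
    splittable = split_idx[counts[split_idx] >= 2]

    all_aa = [aa]
    all_counts = [counts.copy()]
    if len(splittable):
        part = (all_counts[0][splittable] * rng.uniform(0.2, 0.8, len(splittable))
                ).round().astype(int)
        part = np.clip(part, 1, all_counts[0][splittable] - 1)
        all_counts[0][splittable] -= part
        all_aa.append(aa[splittable])
        all_counts.append(part)
    aa_rows = np.concatenate(all_aa)
    count_rows = np.concatenate(all_counts)
    frame_rows = np.full(len(aa_rows), "In", dtype=object)

    n_nonprod = int(round(config.nonproductive_fraction * n))
    if n_nonprod:
        np_ids = rng.integers(0, 19 ** 8, size=n_nonprod)
        aa_rows = np.concatenate([aa_rows, _make_cdr3aa(np_ids)])
        count_rows = np.concatenate(
            [count_rows, rng.integers(1, 5, size=n_nonprod)])
        frame_rows = np.concatenate(
            [frame_rows, rng.choice(["Out", "Stop"], size=n_nonprod)])

    m = len(aa_rows)
    v, d, j = _sample_genes(rng, m, v_probs)
    df = pd.DataFrame({
        "rearrangement": _random_nt(rng, m),
        "amino_acid": aa_rows,
        "v_gene": v,
        "d_gene": d,
        "j_gene": j,
        "templates": count_rows.astype(int),
        "frame_type": frame_rows,
    })
    order = rng.permutation(m)
    return RearrangementTable(sample_id, df.iloc[order].reset_index(drop=True))


def _copula_counts(
    rng: np.random.Generator, analyte_log2: np.ndarray, tau: float
) -> np.ndarray:
    """Clone counts rank-linked to an analyte via a Gaussian copula.

    Correlation of the latent normals is sin(pi*tau/2), the Greiner relation
    that maps a bivariate-normal correlation to its Kendall tau.
    """
    rho = np.sin(np.pi * tau / 2.0)
    z_analyte = stats.norm.ppf(
        (stats.rankdata(analyte_log2) - 0.5) / len(analyte_log2))
    z = rho * z_analyte + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.standard_normal(
        len(analyte_log2))
    return np.maximum(1, np.round(np.exp(np.log(50.0) + 1.0 * z))).astype(int)


def generate_repertoires(
    config: CohortConfig,
    blood_latent_log2: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list, pd.DataFrame, dict]:
    """Generate every rearrangement table plus metadata and ground-truth bits.

    ``blood_latent_log2`` (patients x analytes, unmasked log2 blood levels)
    is required when sequence–cytokine links are planted; it anchors the
    Gaussian copula.  Emits one blood and one CSF table per MS/control
    patient and one blood table per healthy-reference individual.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    if config.planted_links and blood_latent_log2 is None:
        raise ValueError("planted_links require blood analyte values for the copula")

    ms = config.ms_patients()
    ctrl = config.ctrl_patients()
    healthy = config.healthy_patients()

    v_probs_base = 1.0 / np.arange(2, 2 + len(TRBV_GENES))
    v_probs_base /= v_probs_base.sum()
    v_probs_ms = v_probs_base.copy()
    if config.trbv_shift is not None:
        gene, factor = config.trbv_shift
        v_probs_ms[TRBV_GENES.index(gene)] *= factor
        v_probs_ms /= v_probs_ms.sum()

    # planted link sequences: inserted into every MS blood repertoire with
    # copula-linked counts
    link_seqs: dict[str, str] = {}
    link_counts: dict[str, np.ndarray] = {}
    for label, analyte, tau in config.planted_links:
        seq = _label_to_sequence(label)
        link_seqs[label] = seq
        link_counts[seq] = _copula_counts(
            rng, blood_latent_log2.loc[ms, analyte].to_numpy(), tau)

    # planted MS-enriched PRS sequences with per-individual presence draws
    prs_ids = np.arange(config.n_ms_enriched_prs) + 7 * 19 ** 7
    prs_seqs = list(_make_cdr3aa(prs_ids)) if config.n_ms_enriched_prs else []
    prs_in_ms = rng.random((len(prs_seqs), config.n_ms)) < config.prs_occurrence_ms
    if config.n_ms >= 2:
        for k in range(len(prs_seqs)):  # a PRS must reach >=2 MS CSF samples
            while prs_in_ms[k].sum() < 2:
                prs_in_ms[k, rng.integers(0, config.n_ms)] = True
    prs_in_healthy = (rng.random((len(prs_seqs), config.n_healthy_ref))
                      < config.prs_occurrence_healthy)

    pool = config.public_pool_size
    tables: list[RearrangementTable] = []
    meta_rows = []
    realized_sharing: dict[str, float] = {}

    def _draw_clone_sets(n_csf: int, n_blood: int, patient_idx: int):
        """Public draws disjoint within a patient; private ids disjoint by
        (patient, compartment) so chance CSF/blood overlap is impossible."""
        n_pub_csf = int(round(config.public_clone_fraction * n_csf))
        n_pub_blood = int(round(config.public_clone_fraction * n_blood))
        pub = rng.choice(pool, size=n_pub_csf + n_pub_blood, replace=False)
        base = 19 ** 8 // 2
        priv_csf = base + (2 * patient_idx) * 10 ** 6 + np.arange(n_csf - n_pub_csf)
        priv_blood = base + (2 * patient_idx + 1) * 10 ** 6 + np.arange(n_blood - n_pub_blood)
        csf_aa = _make_cdr3aa(np.concatenate([pub[:n_pub_csf], priv_csf]))
        blood_aa = _make_cdr3aa(np.concatenate([pub[n_pub_csf:], priv_blood]))
        return csf_aa, blood_aa

    all_patients = [(p, "MS") for p in ms] + [(p, "CTRL") for p in ctrl]
    for pidx, (patient, group) in enumerate(all_patients):
        share_rate = (config.sharing_rate_ms if group == "MS"
                      else config.sharing_rate_ctrl)
        csf_aa, blood_aa = _draw_clone_sets(
            config.clones_per_csf, config.clones_per_blood, pidx)
        # sharing: copy a Binomial(n_csf, rate) subset of CSF clones into the
        # blood repertoire, displacing random blood clones; blood counts are
        # the displaced clones' own (i.e. re-drawn relative to CSF)
        n_shared = rng.binomial(config.clones_per_csf, share_rate)
        if n_shared:
            src = rng.choice(len(csf_aa), size=n_shared, replace=False)
            dst = rng.choice(len(blood_aa), size=n_shared, replace=False)
            blood_aa = blood_aa.copy()
            blood_aa[dst] = csf_aa[src]
        realized_sharing[patient] = n_shared / config.clones_per_csf

        csf_counts = _zipf_counts(rng, len(csf_aa), config.zipf_exponent)
        blood_counts = _zipf_counts(rng, len(blood_aa), config.zipf_exponent)

        # planted PRS sequences live in MS CSF
        if group == "MS":
            ms_idx = ms.index(patient)
            extra = [prs_seqs[k] for k in range(len(prs_seqs)) if prs_in_ms[k, ms_idx]]
            if extra:
                csf_aa = np.concatenate([csf_aa, extra])
                csf_counts = np.concatenate(
                    [csf_counts, rng.integers(2, 40, size=len(extra))])
            link_extra = [(seq, link_counts[seq][ms_idx]) for seq in link_counts]
            if link_extra:
                blood_aa = np.concatenate([blood_aa, [s for s, _ in link_extra]])
                blood_counts = np.concatenate(
                    [blood_counts, [c for _, c in link_extra]])

        v_probs = v_probs_ms if group == "MS" else v_probs_base
        tables.append(_build_table(rng, f"{patient}_CSF", csf_aa, csf_counts,
                                   config, v_probs))
        tables.append(_build_table(rng, f"{patient}_blood", blood_aa, blood_counts,
                                   config, v_probs))
        hla_p = (config.hla_prevalence_ms if group == "MS"
                 else config.hla_prevalence_ctrl)
        hla = bool(rng.random() < hla_p)
        age = int(rng.normal(36, 9))
        sex = str(rng.choice(["F", "M"]))
        edss = float(rng.choice([0, 1, 1, 1.5, 2, 3])) if group == "MS" else 0.0
        for compartment in ("CSF", "blood"):
            meta_rows.append({"patient_id": patient, "compartment": compartment,
                              "group": group, "hla_drb1_1501": hla, "age": age,
                              "sex": sex, "edss": edss})

    for hidx, patient in enumerate(healthy):
        n = config.clones_per_blood
        n_pub = int(round(config.public_clone_fraction * n))
        pub = rng.choice(pool, size=n_pub, replace=False)
        priv = 19 ** 8 // 2 + (2 * (len(all_patients) + hidx)) * 10 ** 6 + np.arange(n - n_pub)
        aa = _make_cdr3aa(np.concatenate([pub, priv]))
        counts = _zipf_counts(rng, len(aa), config.zipf_exponent)
        extra = [prs_seqs[k] for k in range(len(prs_seqs)) if prs_in_healthy[k, hidx]]
        if extra:
            aa = np.concatenate([aa, extra])
            counts = np.concatenate([counts, rng.integers(2, 40, size=len(extra))])
        tables.append(_build_table(rng, f"{patient}_blood", aa, counts,
                                   config, v_probs_base))
        meta_rows.append({"patient_id": patient, "compartment": "blood",
                          "group": "HEALTHY_REF",
                          "hla_drb1_1501": False,
                          "age": int(rng.normal(40, 12)),
                          "sex": str(rng.choice(["F", "M"])), "edss": 0.0})

    from .io_formats import METADATA_COLUMNS

    metadata = validate_metadata(pd.DataFrame(meta_rows, columns=METADATA_COLUMNS))
    extras = {
        "planted_link_sequences": link_seqs,
        "planted_prs_sequences": prs_seqs,
        "realized_sharing": realized_sharing,
    }
    return tables, metadata, extras


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic study (cytokines + repertoires + metadata)."""
    panels, latent, realized = generate_cytokines(config)
    tables, metadata, extras = generate_repertoires(config, latent["blood"])
    truth = GroundTruth(
        planted_fold_changes=dict(config.planted_fold_changes),
        realized_fold_changes=realized["fold_changes"],
        correlation_blocks=[(list(b), r) for b, r in config.correlation_blocks],
        realized_block_correlations=realized["block_correlations"],
        planted_links=[list(link) for link in config.planted_links],
        planted_link_sequences=extras["planted_link_sequences"],
        planted_prs_sequences=list(extras["planted_prs_sequences"]),
        realized_sharing=extras["realized_sharing"],
        sharing_rate_ms=config.sharing_rate_ms,
        sharing_rate_ctrl=config.sharing_rate_ctrl,
    )
    return SyntheticCohort(config, panels, latent, tables, metadata, truth)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write the cohort as TSV/CSV/JSON files; returns a manifest.

    Layout: ``repertoires/<patient>_<compartment>.tsv``, one cytokine CSV per
    compartment, ``metadata.csv`` and ``ground_truth.json``.  The manifest
    lists every file with its data row count.
    """
    directory = Path(directory)
    (directory / "repertoires").mkdir(parents=True, exist_ok=True)
    files = []
    for table in cohort.tables:
        rel = f"repertoires/{table.sample_id}.tsv"
        write_rearrangements(table, directory / rel)
        files.append({"path": rel, "rows": int(len(table))})
    for compartment, panel in cohort.panels.items():
        rel = f"cytokines_{compartment}.csv"
        write_cytokines(panel, directory / rel)
        files.append({"path": rel, "rows": int(len(panel.values))})
    write_metadata(cohort.metadata, directory / "metadata.csv")
    files.append({"path": "metadata.csv", "rows": int(len(cohort.metadata))})
    (directory / "ground_truth.json").write_text(cohort.ground_truth.to_json())
    files.append({"path": "ground_truth.json", "rows": 1})
    manifest = {"n_files": len(files), "files": files,
                "seed": cohort.config.seed}
    if not cohort.tables:
        warnings.warn("writing an empty cohort: no repertoire files emitted")
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
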