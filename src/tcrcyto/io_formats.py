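"""Readers and writers for every external format the pipeline touches.

Formats
-------
* rearrangement TSV (immunoSEQ dialect): one row per clonotype with columns
  ``rearrangement`` (CDR3 nucleotide), ``amino_acid`` (CDR3.aa), ``v_gene``,
  ``d_gene``, ``j_gene``, ``templates`` (non-negative integer) and
  ``frame_type`` ("In" marks a productive, in-frame rearrangement).  Real
  exports carry many more columns; extras are preserved opaquely and never
  rejected.
* cytokine panel CSV: rows = samples, columns = analytes, empty cell =
  concentration below the detection threshold ("not detected").
* cohort metadata CSV: one row per (patient, compartment) sample.
* GraphML / edge TSV for correlation networks.

Validation failures always carry file, row and column context.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .categories import ANALYTE_CATEGORIES, canonical_analyte

REARRANGEMENT_COLUMNS = [
    "rearrangement",
    "amino_acid",
    "v_gene",
    "d_gene",
    "j_gene",
    "templates",
    "frame_type",
]

GROUPS = ("MS", "CTRL", "HEALTHY_REF")
COMPARTMENTS = ("CSF", "blood")


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class ValidationError(ValueError):
    """A value violates its contract; message carries row/column context."""


@dataclass
class RearrangementTable:
    """One sample's clonotype rows.

    ``data`` holds at least :data:`REARRANGEMENT_COLUMNS`; extra columns are
    kept untouched.  ``productive`` is derived from ``frame_type == "In"``.
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REARRANGEMENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(
                f"sample {self.sample_id!r}: missing required column(s) {missing}"
            )
        templates = self.data["templates"]
        bad = np.flatnonzero(templates.to_numpy() < 0)
        if bad.size:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative templates at row {bad[0] + 1} "
                f"(value {templates.iloc[bad[0]]})"
            )
        prod = self.productive_mask()
        empty_aa = prod & (self.data["amino_acid"].astype(str).str.len() == 0)
        if empty_aa.any():
            row = int(np.flatnonzero(empty_aa.to_numpy())[0]) + 1
            raise ValidationError(
                f"sample {self.sample_id!r}: productive row {row} has empty amino_acid"
            )

    def productive_mask(self) -> pd.Series:
        return self.data["frame_type"].astype(str).eq("In")

    def productive(self) -> pd.DataFrame:
        """Rows with an in-frame rearrangement (the default analysis set)."""
        return self.data[self.productive_mask()]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CytokinePanel:
    """Samples x analytes concentration matrix (pg/mL) with detection mask.

    ``values`` stores NaN where the assay reported "not detected"; the mask
    is therefore ``values.notna()``.  ``category_map`` must cover every
    analyte column.
    """

    values: pd.DataFrame
    category_map: Mapping[str, str] = field(default_factory=lambda: ANALYTE_CATEGORIES)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        unmapped = [a for a in self.values.columns if a not in self.category_map]
        if unmapped:
            raise SchemaError(f"analytes missing from category map: {unmapped}")
        if (self.values.to_numpy() < 0).any():
            bad = self.values.stack()
            bad = bad[bad < 0]
            sample, analyte = bad.index[0]
            raise ValidationError(
                f"negative concentration for sample {sample!r}, analyte {analyte!r}: "
                f"{bad.iloc[0]}"
            )

    @property
    def detected(self) -> pd.DataFrame:
        return self.values.notna()

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def subset(self, samples: Iterable[str]) -> "CytokinePanel":
        return CytokinePanel(self.values.loc[list(samples)], self.category_map)


METADATA_COLUMNS = ["patient_id", "compartment", "group", "hla_drb1_1501", "age", "sex", "edss"]


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the per-sample metadata table; returns it unchanged."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata: missing column(s) {missing}")
    dup = meta.duplicated(subset=["patient_id", "compartment"])
    if dup.any():
        pairs = meta.loc[dup, ["patient_id", "compartment"]].to_records(index=False)
        raise ValidationError(f"metadata: duplicate (patient, compartment) pairs {list(pairs)}")
    bad_group = set(meta["group"]) - set(GROUPS)
    if bad_group:
        raise ValidationError(f"metadata: unknown group label(s) {sorted(bad_group)}")
    bad_comp = set(meta["compartment"]) - set(COMPARTMENTS)
    if bad_comp:
        raise ValidationError(f"metadata: unknown compartment label(s) {sorted(bad_comp)}")
    return meta


# ---------------------------------------------------------------------------
# rearrangement tables


def read_rearrangements(path: str | Path, sample_id: str | None = None) -> RearrangementTable:
    """Read one immunoSEQ-dialect TSV; ``sample_id`` defaults to the file stem."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"rearrangement": str, "amino_acid": str})
    missing = [c for c in REARRANGEMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if len(df):
        templates = pd.to_numeric(df["templates"], errors="coerce")
        if templates.isna().any():
            row = int(templates.index[templates.isna()][0]) + 1
            raise ValidationError(f"{path}: non-numeric templates at row {row}")
        if (templates < 0).any():
            row = int(templates.index[templates < 0][0]) + 1
            raise ValidationError(
                f"{path}: negative templates at row {row} (column 'templates')"
            )
        df["templates"] = templates.astype(int)
        df["amino_acid"] = df["amino_acid"].fillna("")
    else:
        df = df.astype({"templates": int})
    return RearrangementTable(sample_id or path.stem, df)


def write_rearrangements(table: RearrangementTable, path: str | Path) -> None:
    cols = REARRANGEMENT_COLUMNS + [
        c for c in table.data.columns if c not in REARRANGEMENT_COLUMNS
    ]
    table.data.to_csv(path, sep="\t", index=False, columns=cols)


# ---------------------------------------------------------------------------
# cytokine panels and metadata


def read_cytokines(
    path: str | Path, category_map: Mapping[str, str] | None = None
) -> CytokinePanel:
    """Read a panel CSV (first column = sample id, empty cell = not detected)."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    df.index.name = None
    df.columns = [canonical_analyte(c) for c in df.columns]
    cmap = ANALYTE_CATEGORIES if category_map is None else category_map
    unmapped = [a for a in df.columns if a not in cmap]
    if unmapped:
        raise SchemaError(f"{path}: analytes missing from category map: {unmapped}")
    try:
        return CytokinePanel(df, cmap)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from err


def write_cytokines(panel: CytokinePanel, path: str | Path) -> None:
    panel.values.to_csv(path, index_label="sample_id", na_rep="")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(meta).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# networks


def write_network(network, path: str | Path, dialect: str = "graphml") -> None:
    """Serialise a correlation network.

    ``graphml`` writes the full annotated graph; ``edge_tsv`` writes one row
    per edge sorted by |r| descending (ties broken by node pair) so diffs are
    reproducible.
    """
    path = Path(path)
    if dialect == "graphml":
        nx.write_graphml(network.graph, path)
    elif dialect == "edge_tsv":
        rows = [
            {
                "analyte_a": a,
                "analyte_b": b,
                "r": d["r"],
                "raw_p": d["raw_p"],
                "adjusted_p": d["adjusted_p"],
                "sign": d["sign"],
            }
            for a, b, d in network.graph.edges(data=True)
        ]
        rows.sort(key=lambda row: (-abs(row["r"]), row["analyte_a"], row["analyte_b"]))
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=["analyte_a", "analyte_b", "r", "raw_p", "adjusted_p", "sign"],
                delimiter="\t",
            )
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ValueError(f"unknown network dialect {dialect!r}")


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# sequence annotation (join against a user-supplied table, e.g. a McPAS export)


def read_annotation_table(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV mapping CDR3.aa -> label.

    Duplicate keys with conflicting labels are an error; exact duplicates are
    collapsed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: annotation table needs >=2 columns (cdr3_aa, label)")
    key_col, label_col = df.columns[:2]
    conflicts = (
        df.groupby(key_col)[label_col].nunique().loc[lambda s: s > 1].index.tolist()
    )
    if conflicts:
        raise ValidationError(f"{path}: conflicting labels for sequence(s) {conflicts}")
    return dict(zip(df[key_col], df[label_col]))


def annotate_sequences(
    sequences: Iterable[str], annotation_table: Mapping[str, str]
) -> pd.DataFrame:
    """Label sequences by exact full-string CDR3.aa match (100 % identity).

    Non-matches get label ``None``.
    """
    seqs = list(sequences)
    return pd.DataFrame(
        {"cdr3_aa": seqs, "label": [annotation_table.get(s) for s in seqs]}
    )
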