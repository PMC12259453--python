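"""End-to-end orchestration: simulate -> cytokines -> network -> repertoire
-> prs -> integrate.

Each stage reads files written by earlier stages (fail-fast when missing),
writes its artifacts into the output directory exactly once, logs every
exclusion it makes (skipped analytes, dropped patients, removed samples)
and contributes a record to the machine-readable run report.  All
thresholds default to the standard analysis values so a bare run reproduces
the reference procedure on synthetic data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlation_network import (
    build_network,
    layout_force_directed,
    network_summary,
    pearson_all_pairs,
)
from .cytokine_stats import (
    compare_groups,
    linkage_order,
    preprocess_panel,
    zscore_rows,
)
from .io_formats import (
    read_cytokines,
    read_metadata,
    read_rearrangements,
    write_network,
)
from .prs_clustering import build_rank_matrix, cluster_occurrence_test, identify_prs, kmeans_two
from .repertoire_metrics import (
    aggregate_by_cdr3aa,
    classify_clones,
    fisher_2x2,
    sample_statistics,
    sharing_summary,
    trbv_usage,
)
from .synthetic_cohort import CohortConfig, generate_cohort, write_cohort
from .tcr_cytokine import associate, select_predominant, select_public, tabulate

log = logging.getLogger("tcrcyto")

STAGES = ["simulate", "cytokines", "network", "repertoire", "prs", "integrate"]


@dataclass
class PipelineConfig:
    """Thresholds and paths for one pipeline run (flat key=value file)."""

    data_dir: str = "cohort"
    out_dir: str = "results"
    seed: int = 0
    r_min: float = 0.6
    alpha: float = 0.05
    tau_min: float = 0.5
    top_n: int = 10
    min_count: int = 2
    min_patients: int = 2
    min_ms: int = 5
    enrichment_fold: float = 10.0
    winsor_tail: float = 0.125
    outlier_k: float = 2.0
    min_pairs_corr: int = 4
    min_pairs_assoc: int = 5
    productive_only: bool = True
    bh_scope: str = "global"
    # synthetic-cohort overrides used by the simulate stage
    n_ms: int = 24
    n_ctrl: int = 9
    n_healthy_ref: int = 88
    clones_per_blood: int = 4000
    clones_per_csf: int = 1000

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.r_min <= 1:
            raise ValueError("r_min must be in [0, 1]")
        if not 0 <= self.tau_min <= 1:
            raise ValueError("tau_min must be in [0, 1]")
        if not 0 <= self.winsor_tail < 0.5:
            raise ValueError("winsor_tail must be in [0, 0.5)")
        if self.outlier_k < 0 or self.enrichment_fold <= 0:
            raise ValueError("outlier_k must be >= 0 and enrichment_fold > 0")
        for name in ("top_n", "min_count", "min_patients", "min_ms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Parse a flat ``key = value`` config file; overrides win."""
    values: dict = {}
    fields = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = raw
    cfg = PipelineConfig()
    for key, raw in values.items():
        current = getattr(cfg, key)
        if isinstance(current, bool):
            setattr(cfg, key, raw.lower() in ("1", "true", "yes"))
        elif isinstance(current, int):
            setattr(cfg, key, int(raw))
        elif isinstance(current, float):
            setattr(cfg, key, float(raw))
        else:
            setattr(cfg, key, raw)
    for key, value in overrides.items():
        if value is not None:
            setattr(cfg, key, value)
    cfg.validate()
    return cfg


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing required input {path} "
            "(run the earlier stage first)")
    return path


def _read_cohort(cfg: PipelineConfig):
    data = Path(cfg.data_dir)
    meta = read_metadata(_require(data / "metadata.csv", "read"))
    tables = [
        read_rearrangements(p)
        for p in sorted((data / "repertoires").glob("*.tsv"))
    ]
    return meta, tables


def _patient_groups(meta: pd.DataFrame) -> pd.Series:
    return meta.drop_duplicates("patient_id").set_index("patient_id")["group"]


class PipelineRun:
    """Stage driver accumulating a run report."""

    def __init__(self, cfg: PipelineConfig):
        cfg.validate()
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.report: dict = {
            "version": __version__,
            "seed": cfg.seed,
            "config": dataclasses.asdict(cfg),
            "stages": {},
        }

    # -- stages -----------------------------------------------------------
    def simulate(self) -> dict:
        cfg = self.cfg
        cohort_cfg = CohortConfig(
            n_ms=cfg.n_ms, n_ctrl=cfg.n_ctrl, n_healthy_ref=cfg.n_healthy_ref,
            clones_per_blood=cfg.clones_per_blood, clones_per_csf=cfg.clones_per_csf,
            seed=cfg.seed)
        cohort = generate_cohort(cohort_cfg)
        manifest = write_cohort(cohort, cfg.data_dir)
        rec = {"n_files": manifest["n_files"],
               "n_tables": len(cohort.tables),
               "n_samples_meta": int(len(cohort.metadata))}
        log.info("simulate: wrote %d files to %s", manifest["n_files"], cfg.data_dir)
        self.report["stages"]["simulate"] = rec
        return rec

    def cytokines(self) -> dict:
        cfg = self.cfg
        data = Path(cfg.data_dir)
        meta = read_metadata(_require(data / "metadata.csv", "cytokines"))
        groups = _patient_groups(meta)
        rec: dict = {}
        for compartment in ("CSF", "blood"):
            panel = read_cytokines(
                _require(data / f"cytokines_{compartment}.csv", "cytokines"))
            pg = groups.reindex(panel.values.index)
            processed, outliers = preprocess_panel(
                panel, pg, outlier_k=cfg.outlier_k, winsor_tail=cfg.winsor_tail)
            for sample in outliers.removed_samples:
                log.info("cytokines[%s]: removed outlier sample %s", compartment, sample)
            kept_panel = panel.subset(processed.index)
            comparison = compare_groups(kept_panel, pg.reindex(processed.index),
                                        alpha=cfg.alpha)
            for analyte in comparison.skipped:
                log.info("cytokines[%s]: skipped analyte %s (degenerate groups)",
                         compartment, analyte)
            comparison.table.to_csv(self.out / f"group_comparison_{compartment}.tsv",
                                    sep="\t")
            processed.to_csv(self.out / f"processed_{compartment}.tsv", sep="\t")
            rows = processed.T  # rows = analytes for heatmaps
            scalable = rows.index[rows.notna().sum(axis=1) >= 2]
            for analyte in rows.index.difference(scalable):
                log.info("cytokines[%s]: analyte %s not scaled (<2 detected)",
                         compartment, analyte)
            scaled = zscore_rows(rows.loc[scalable])
            scaled = scaled.loc[linkage_order(scaled)]
            scaled.to_csv(self.out / f"zscored_{compartment}.tsv", sep="\t")
            rec[compartment] = {
                "n_samples": int(len(processed)),
                "removed_samples": outliers.removed_samples,
                "n_analytes_tested": int(len(comparison.table)),
                "n_significant": int(comparison.table["significant"].sum())
                if len(comparison.table) else 0,
            }
        self.report["stages"]["cytokines"] = rec
        return rec

    def network(self) -> dict:
        cfg = self.cfg
        rec: dict = {}
        for compartment in ("CSF", "blood"):
            _require(Path(self.out) / f"processed_{compartment}.tsv", "network")
        meta = read_metadata(_require(Path(cfg.data_dir) / "metadata.csv", "network"))
        groups = _patient_groups(meta)
        for compartment in ("CSF", "blood"):
            processed = pd.read_csv(self.out / f"processed_{compartment}.tsv",
                                    sep="\t", index_col=0)
            for group in ("MS", "CTRL"):
                members = [s for s in processed.index if groups.get(s) == group]
                pairs = pearson_all_pairs(processed.loc[members],
                                          min_pairs=cfg.min_pairs_corr)
                for a, b, reason in pairs.attrs["skipped"]:
                    log.debug("network[%s/%s]: skipped pair %s-%s (%s)",
                              group, compartment, a, b, reason)
                if pairs.attrs["skipped"]:
                    log.info("network[%s/%s]: %d pairs skipped (see DEBUG)",
                             group, compartment, len(pairs.attrs["skipped"]))
                net = build_network(pairs, r_min=cfg.r_min, alpha=cfg.alpha)
                layout_force_directed(net, seed=cfg.seed)
                tag = f"{group}_{compartment}"
                write_network(net, self.out / f"network_{tag}.graphml", "graphml")
                write_network(net, self.out / f"network_{tag}.tsv", "edge_tsv")
                summary = network_summary(net)
                (self.out / f"network_{tag}.json").write_text(
                    json.dumps(summary, indent=2, sort_keys=True))
                rec[tag] = {"n_edges": summary["n_edges"],
                            "n_positive": summary["n_positive"],
                            "n_negative": summary["n_negative"]}
        self.report["stages"]["network"] = rec
        return rec

    def repertoire(self) -> dict:
        cfg = self.cfg
        meta, tables = _read_cohort(cfg)
        groups = _patient_groups(meta)
        clinical = [t for t in tables
                    if groups.get(t.sample_id.rpartition("_")[0]) in ("MS", "CTRL")]
        ledger = aggregate_by_cdr3aa(clinical, productive_only=cfg.productive_only)
        stats_table, welch = sample_statistics(ledger, groups)
        stats_table.to_csv(self.out / "sample_statistics.tsv", sep="\t", index=False)
        share = sharing_summary(ledger, groups)
        for patient in share.excluded:
            log.info("repertoire: excluded unpaired patient %s", patient)
        share.per_patient.to_csv(self.out / "sharing.tsv", sep="\t")
        taxonomy = classify_clones(ledger)
        tax_counts = (taxonomy.groupby(["sharing", "public"]).size()
                      .rename("n").reset_index())
        tax_counts.to_csv(self.out / "clone_taxonomy.tsv", sep="\t", index=False)
        usage_rec = {}
        for compartment in ("CSF", "blood"):
            subset = [t for t in clinical if t.sample_id.endswith(f"_{compartment}")]
            usage, comparison = trbv_usage(subset, groups, alpha=cfg.alpha)
            usage.to_csv(self.out / f"trbv_usage_{compartment}.tsv", sep="\t")
            comparison.to_csv(self.out / f"trbv_comparison_{compartment}.tsv", sep="\t")
            usage_rec[compartment] = {
                "n_genes": int(usage.shape[1]),
                "n_significant": int(comparison["significant"].sum())
                if len(comparison) else 0}
        # HLA carriage 2x2 (MS vs CTRL)
        hla = meta.drop_duplicates("patient_id").set_index("patient_id")
        ms_pos = int(hla.loc[hla["group"] == "MS", "hla_drb1_1501"].sum())
        ms_neg = int((hla["group"] == "MS").sum()) - ms_pos
        ct_pos = int(hla.loc[hla["group"] == "CTRL", "hla_drb1_1501"].sum())
        ct_neg = int((hla["group"] == "CTRL").sum()) - ct_pos
        or_cmle, p = fisher_2x2([[ms_pos, ms_neg], [ct_pos, ct_neg]])
        rec = {
            "n_samples": int(len(ledger.totals)),
            "n_paired_patients": int(len(share.per_patient)),
            "excluded_patients": share.excluded,
            "group_means_pct_shared_of_csf":
                {k: float(v) for k, v in
                 share.group_means.get("pct_shared_of_csf", pd.Series()).items()},
            "welch_tests": {f"{c}:{m}": t for (c, m), t in welch.items()},
            "sharing_welch": share.tests,
            "trbv": usage_rec,
            "hla_fisher": {"table": [[ms_pos, ms_neg], [ct_pos, ct_neg]],
                           "odds_ratio_cmle": or_cmle, "p": p},
        }
        (self.out / "repertoire_summary.json").write_text(
            json.dumps(rec, indent=2, sort_keys=True, default=float))
        self.report["stages"]["repertoire"] = rec
        return rec

    def prs(self) -> dict:
        cfg = self.cfg
        meta, tables = _read_cohort(cfg)
        groups = _patient_groups(meta)
        ms = sorted(groups.index[groups == "MS"])
        healthy = sorted(groups.index[groups == "HEALTHY_REF"])
        ledger_all = aggregate_by_cdr3aa(tables, productive_only=cfg.productive_only)
        ms_csf = ledger_all.restrict(patients=ms, compartment="CSF")
        prs = identify_prs(ms_csf, top_n=cfg.top_n, min_count=cfg.min_count,
                           min_patients=cfg.min_patients)
        prs.table.to_csv(self.out / "prs.tsv", sep="\t")
        comparison = ledger_all.restrict(patients=ms + healthy)
        rank = build_rank_matrix(prs, comparison, groups)
        assignment = kmeans_two(rank, seed=cfg.seed)
        occurrence = cluster_occurrence_test(assignment)
        pd.DataFrame({"cluster": assignment.labels}).join(
            assignment.pca_coords).to_csv(self.out / "prs_clusters.tsv", sep="\t")
        n_crit1 = int(prs.table["top10_csf"].sum())
        n_crit2 = int(prs.table["multi_patient_csf"].sum())
        rec = {
            "n_prs": len(prs),
            "n_criterion1": n_crit1,
            "n_criterion2": n_crit2,
            "n_ms_dimensions": len(ms),
            "n_healthy_dimensions": len(healthy),
            "n_ms_associated": int((assignment.labels == "ms_associated").sum()),
            "occurrence": occurrence,
            "pca_explained_variance": [float(v) for v in assignment.explained_variance],
        }
        (self.out / "prs_summary.json").write_text(
            json.dumps(rec, indent=2, sort_keys=True, default=float))
        self.report["stages"]["prs"] = rec
        return rec

    def integrate(self) -> dict:
        cfg = self.cfg
        data = Path(cfg.data_dir)
        meta, tables = _read_cohort(cfg)
        groups = _patient_groups(meta)
        ms = sorted(groups.index[groups == "MS"])
        ctrl = sorted(groups.index[groups == "CTRL"])
        blood_tables = [t for t in tables if t.sample_id.endswith("_blood")
                        and t.sample_id.rpartition("_")[0] in set(ms) | set(ctrl)]
        ledger = aggregate_by_cdr3aa(blood_tables, productive_only=cfg.productive_only)
        public = select_public(ledger, min_samples=cfg.min_patients)
        predominant = select_predominant(
            public, ledger, groups.reindex(ms + ctrl),
            min_ms=cfg.min_ms, enrichment_fold=cfg.enrichment_fold)
        predominant.table.to_csv(self.out / "predominant.tsv", sep="\t")
        panel = read_cytokines(_require(data / "cytokines_blood.csv", "integrate"))
        associations = associate(predominant, panel, ledger, ms,
                                 tau_min=cfg.tau_min, alpha=cfg.alpha,
                                 min_pairs=cfg.min_pairs_assoc,
                                 bh_scope=cfg.bh_scope)
        for seq, analyte, reason in associations.skipped:
            log.debug("integrate: skipped %s x %s (%s)", seq, analyte, reason)
        associations.table.to_csv(self.out / "associations.tsv", sep="\t", index=False)
        tallies = tabulate(associations)
        (self.out / "association_tallies.json").write_text(
            json.dumps(tallies, indent=2, sort_keys=True))
        rec = {
            "n_public": len(public),
            "n_predominant": len(predominant),
            "n_tested_pairs": int(len(associations.table)),
            "n_significant": tallies["n_significant"],
            "n_sequences": tallies["n_sequences"],
            "n_analytes": tallies["n_analytes"],
        }
        self.report["stages"]["integrate"] = rec
        return rec

    # -- driver -----------------------------------------------------------
    def run(self, subcommand: str) -> dict:
        if subcommand == "all":
            order = STAGES
        elif subcommand in STAGES:
            order = [subcommand]
        else:
            raise ValueError(f"unknown subcommand {subcommand!r}")
        for stage in order:
            log.info("running stage %s", stage)
            getattr(self, stage)()
        report_path = self.out / "report.json"
        report_path.write_text(json.dumps(self.report, indent=2, sort_keys=True,
                                          default=float))
        return self.report
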