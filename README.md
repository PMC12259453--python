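# tcrcyto

Integrated cytokine-network and TCR-repertoire analysis for paired
cerebrospinal-fluid (CSF) / blood cohorts, built around the multiple
sclerosis (MS) setting: a small clinical cohort (MS patients vs
non-inflammatory controls) profiled with a 48-analyte multiplex cytokine
panel and bulk TCRβ immunosequencing of both compartments, compared against
a large blood-only "healthy reference" repertoire cohort.

It is aimed at neuroimmunology groups who have immunoSEQ-style
rearrangement exports and a Bio-Plex-style cytokine table and want the full
chain — preprocessing, correlation networks, clone accounting,
disease-associated sequence clusters and TCR–cytokine association — as
tested, scriptable code rather than a collection of notebook fragments.
Because the matching clinical data cannot be redistributed, the package
ships a synthetic cohort generator with planted, recoverable structure that
stands in for the deposited data and doubles as the validation harness.

## What it computes

**Cytokine statistics** (`tcrcyto.cytokine_stats`). Within each (analyte,
group): IQR outlier screen (flag x if x < Q1 − 2·IQR or x > Q3 + 2·IQR,
linear-interpolation quartiles), log2(x+1) transform, Winsorization at
12.5 % per tail. Group comparison per analyte by Mann–Whitney U
(exact for small tie-free samples) with Benjamini–Hochberg (BH) control;
fold change = ratio of raw-scale group means. Row z-scoring
((x − mean)/sd) for heatmap export.

**Correlation networks** (`tcrcyto.correlation_network`). Pairwise-complete
Pearson correlations over the preprocessed matrix; edge kept iff |r| ≥ 0.6
and BH-adjusted p < 0.05; isolated analytes retained; clusters = connected
components; seeded Fruchterman–Reingold layout; GraphML / edge-TSV export.

**Repertoire metrics** (`tcrcyto.repertoire_metrics`). Clonotypes sharing a
CDR3 amino-acid sequence are summed into clones per (patient, compartment).
Clone taxonomy: *unique* (one compartment) vs *shared* (both compartments
of a patient) and *private* vs *public* (> 1 individual). Directional
shared-clone percentages (|CSF ∩ blood| / |CSF| and / |blood|) with Welch
tests; Simpson clonality √(Σ pᵢ²); per-sample summary statistics; TRBV
usage proportions with Mann–Whitney/BH comparison; Fisher's exact test
(conditional-MLE odds ratio) for HLA-DRB1\*15:01 carriage.

**PRS clustering** (`tcrcyto.prs_clustering`). Potentially relevant
sequences (PRS) from MS CSF: top-10 by clone count in a patient with count
≥ 2, or present in ≥ 2 MS CSF samples. Per-individual count ranks (rank 1 =
most abundant, absent = tied bottom) over MS + healthy-reference
individuals feed k-means (k = 2); the cluster with higher MS occurrence is
the MS-associated cluster; PCA coordinates for inspection.

**TCR–cytokine integration** (`tcrcyto.tcr_cytokine`). Public sequences
(≥ 2 individuals) filtered to MS-predominant ones (≥ 5 MS patients and no
controls, or ≥ 10× mean clone-proportion enrichment); Kendall tau-b between
each sequence's blood clone proportion and each blood cytokine across MS
patients, BH-adjusted jointly; significant iff adjusted p < 0.05 and
|τ| > 0.5; tallies per cytokine and functional category.

**Synthetic cohorts** (`tcrcyto.synthetic_cohort`). Log-normal cytokine
panels with planted group fold changes, equicorrelated analyte blocks and
detection limits; Zipf-distributed clone sizes; controlled CSF→blood
sharing; cross-patient public clones; Gaussian-copula sequence–cytokine
links with target Kendall τ; ground truth echoed to JSON.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (24 MS + 9 controls, paired compartments, 88 healthy
reference repertoires; raw data under `scratch/cohort/`, tables under
`results/`):

```bash
cd analysis
python 01_simulate_cohort.py
python 02_cytokine_differences.py
python 03_correlation_networks.py
python 04_repertoire_overview.py
python 05_prs_clusters.py
python 06_tcr_cytokine_links.py
```

With the default seed this prints, among other things:

```
CSF: 2 analyte(s) differ between MS and CTRL (BH-adjusted p < 0.05)
  IP-10: 2.54-fold, adjusted p = 0.00033
  MIP-1a: 2.88-fold, adjusted p = 0.00033

MS_CSF: 6 positive / 0 negative edges, 44 isolated analytes; hubs: G-CSF (3), IL-9 (3), IP-10 (3)

shared CSF clones recovered in blood: MS mean = 0.51% vs CTRL mean = 0.06% (Welch p = 4e-11)

281 PRS (241 via top-10, 40 via multi-patient occurrence), clustered over 24 MS + 88 healthy dimensions
MS-associated cluster: 22 sequences, mean occurrence 13.3% in MS vs 2.0% in healthy (Welch p = 4.9e-05)

436 public sequences -> 6 MS-predominant -> 2 significant associations (2 sequences x 2 cytokines)
  CASSWKPPPISWQYF x SCF (growth factor): tau = +0.74, adjusted p = 0.00012 [ms_only_ge5]
  CASSWKPPPISYQYF x TRAIL (other): tau = -0.66, adjusted p = 0.00088 [ms_only_ge5]
```

Reading: the two analytes planted at 2.57× and 1.91× in MS CSF are the only
significant ones (estimates 2.88 and 2.54 at n = 24 vs 9); the planted
four-analyte r = 0.9 block is recovered as the single 6-edge component in
MS CSF; the planted sharing rates (0.5 % vs 0.1 % of CSF clones) and the
planted sequence–cytokine links (τ = +0.7 with SCF, −0.6 with TRAIL) come
back at their target values and nothing else is flagged.

The same stages are available as a CLI (`tcrcyto --seed 1 --data-dir
cohort --outdir results all`) with a flat key = value config file for
thresholds; every default equals the standard analysis value (r ≥ 0.6,
α = 0.05, |τ| > 0.5, 12.5 % Winsor tails, k = 2 IQR multiplier, …).

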