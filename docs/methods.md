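# Methods

This note documents the statistical procedures, the synthetic-cohort model
behind the validation suite, the numerical conventions, and the design
choices made where the problem was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Cytokine preprocessing and group comparison

The panel is a samples × 48 analyte concentration matrix (pg/mL) with a
"not detected" mask for values below the assay's detection threshold.
Masked cells are excluded from quantiles, tests, means and correlations
(pairwise-complete) throughout; they are never imputed.

The preprocessing order is fixed and tested: (1) outlier screen, (2)
log2(x+1), (3) Winsorization.

* **Outlier screen.** Within each (analyte, group), values outside
  [Q1 − k·IQR, Q3 + k·IQR] are flagged (default k = 2, strict
  inequalities, so an IQR of zero flags nothing). Cells with fewer than
  four detected values cannot support quartiles and are skipped with a
  warning. A *sample* is removed when it is flagged in at least 25 % of
  its evaluable analytes; the source analysis removed one control sample
  by the per-cytokine IQR rule but did not state a sample-level rule, so
  the 25 % threshold is this package's configurable default.
* **Quantile convention.** All quantiles (outlier screen, Winsorizer) use
  linear interpolation between order statistics (R type 7, the numpy
  default), matching the environment the original procedure ran in.
* **Winsorization.** Values are clamped to the 12.5 % / 87.5 % quantiles
  per analyte. Note that with interpolated quantiles, re-winsorizing is an
  exact no-op only when (n−1)·tail lands on an order statistic (e.g. n = 9
  at 12.5 %); elsewhere the clamp bounds of the clamped vector move
  slightly. The tests assert exact idempotence on that domain and
  oracle-equality of the clamp everywhere.
* **Group tests.** Mann–Whitney U per analyte (exact when both groups are
  ≤ 12 and tie-free, otherwise normal approximation with tie and
  continuity correction), BH-adjusted across the analytes of one
  compartment; significance at adjusted p < 0.05. Fold change is the
  ratio of raw-scale group means; the median-based ratio is reported
  alongside because the convention behind published fold values of this
  kind cannot be pinned down — means are primary here.
* **Z-scoring.** Per analyte row, (x − mean)/sd with the n−1 denominator,
  mask-aware; zero-variance rows are set to 0 with a warning so constant
  analytes still render as flat heatmap rows.

## Correlation networks

Pearson r on the preprocessed (log2, Winsorized) matrix for every analyte
pair with ≥ 4 complete observations; two-sided p from the t distribution
with n − 2 df. BH is applied across all pairs of one (group, compartment)
panel — not globally across panels — matching per-panel reporting. An
edge requires |r| ≥ 0.6 *and* adjusted p < 0.05; the absolute-value form
is used even where "r > 0.6" appears in shorthand, and adjusted p is used
uniformly. Isolated analytes remain as degree-0 nodes. "Clusters" are the
connected components of the thresholded graph; a greedy-modularity
refinement is available but labelled heuristic, since the original
sub-clusters were drawn by eye. The Fruchterman–Reingold layout is seeded
and uses |r| as edge weight, so coordinates are reproducible.

## Repertoire accounting

Productive rows (frame_type "In") are the default analysis set; clonotypes
with identical CDR3.aa are summed per (patient, compartment). "Total T
cells" is the full template count including non-productive rows;
"productive templates" the productive subset. Sharing percentages use
distinct-clone counts (not template-weighted) in both directions; the two
directions share their numerator, which the tests assert exactly.
Patients missing a compartment are excluded from sharing and recorded.
Simpson clonality is √(Σ pᵢ²) — the assay vendor's convention, chosen
because the index is usually reported without a formula; the
Shannon-evenness alternative 1 − H/ln R is exposed as an option. The
Fisher 2×2 test reports the conditional-MLE odds ratio (root of the
noncentral hypergeometric mean equation, as R's `fisher.test` does), not
the sample cross-product; the two-sided p sums hypergeometric point
probabilities ≤ the observed one.

## PRS and rank clustering

PRS criteria are applied to the MS CSF ledger: (1) top-10 by summed count
within a patient, ties at the boundary included, count ≥ 2; (2) occurrence
in ≥ 2 MS patients' CSF. Both flags are recorded so the criterion-1,
criterion-2 and union counts are all reported explicitly.

For clustering, each comparison individual (MS or healthy reference)
contributes one dimension: the individual's summed counts over the PRS set
are ranked descending with average ranks for ties, and sequences absent
from an individual share the tied bottom rank — the only convention that
gives every PRS a complete vector when most sequences are missing from
most individuals. Ranking direction does not change the k-means geometry
under tie consistency but is fixed (rank 1 = largest) for reproducibility.
k-means uses k = 2, Euclidean distance, 25 seeded restarts; an
all-identical rank matrix is rejected with a message rather than returning
a meaningless split. The MS-associated label goes to the cluster with the
higher mean occurrence across MS individuals (occurrence = % of a group's
individuals carrying the sequence). PCA (centered, 2 components) fixes
each component's sign by its largest-magnitude loading. Sample exclusions
enter via metadata availability, not hard-coded dimension counts.

## TCR–cytokine association

Clone proportion = summed productive CDR3.aa templates / sample productive
total; a sequence absent from a patient contributes proportion 0 (not
missing), which keeps the rank correlation defined over the whole MS blood
cohort — tau-b's tie correction absorbs the zero ties. Correlations run
over MS patients only (the predominant set is MS-defined; including
controls would mix selection and testing). Kendall tau-b p-values are
exact by permutation enumeration of the concordance statistic for n ≤ 8
(valid under ties) and tie-corrected normal otherwise. BH runs as one
family across all tested (sequence, analyte) pairs by default (matching a
single significance statement over the full association table); a
per-analyte scope is available. Significance requires adjusted p < 0.05
*and* |τ| > 0.5. The log2 enrichment pseudocount defaults to half the
smallest nonzero proportion observed cohort-wide, so rule-A sequences
(control proportion exactly 0) still get finite fold changes.

## Synthetic cohort model

The generator's defaults are the study conditions: 24 MS + 9 control
patients with paired CSF/blood, 88 blood-only healthy-reference
individuals, 48 analytes with the shipped functional category map.

* **Cytokines.** log2 concentrations are multivariate normal: per-analyte
  baselines drawn once (uniform 3.5–8 log2 pg/mL), equicorrelated blocks
  imposed via a Cholesky factor (a block is rejected by name if its
  equicorrelation is not positive semi-definite), within-group noise
  σ = 0.4 on the log2 scale — a spread of ~1.3× around the geometric
  mean, a realistic inter-donor variability for multiplex serum panels.
  MS group means in CSF are shifted by the planted log2 fold changes
  (defaults 2.57× MIP-1α, 1.91× IP-10). Values are exponentiated and then
  censored at the detection limit, so the "not detected" pattern arises
  after noise; four low-abundance analytes (IL-3, IL-5, IL-7, β-NGF) are
  generated mostly below the limit to exercise the mask handling.
* **Repertoires.** Clone counts follow a Zipf law (count ∝ rank^−a,
  default a = 1) with log-normal jitter; the empirical log-log
  rank-frequency slope recovers −a within ±0.3 on deep repertoires
  (tested at 6,000 clones). Sequences are unique random-looking CDR3.aa
  strings from disjoint integer id spaces; a configurable fraction of each
  repertoire (default 10 %) is drawn from a shared public pool, producing
  cross-individual public clones. A patient's CSF and blood draws from
  the pool are disjoint, so within-patient CSF∩blood overlap is produced
  *exclusively* by the sharing mechanism: a Binomial(n_CSF, rate) subset
  of CSF clones is copied into the blood repertoire with the displaced
  blood clones' own counts (counts re-drawn, making recovery estimation
  non-trivial). Defaults: 0.5 % (MS) vs 0.1 % (CTRL). Non-productive
  rows (frame "Out"/"Stop") and clonotype splits (same CDR3.aa, different
  nucleotide rearrangement) are added on top of the clone list.
* **Planted links.** For each (label, analyte, τ) link, a sequence is
  inserted into every MS blood repertoire with counts generated by a
  Gaussian copula against the analyte's latent log2 level using the
  Greiner relation ρ = sin(πτ/2); recovery is tolerance-based because
  tau-b of a copula at n = 24 is noisy (±0.2 bands in the tests).
* **Planted PRS.** MS-enriched CSF sequences occur per MS individual with
  probability 0.20 (topped up to the ≥ 2-patient PRS minimum) and per
  healthy individual with probability 0.04.
* **Determinism.** One integer seed drives a PCG64 stream; identical
  config + seed reproduce the cohort byte-for-byte, which the pipeline
  determinism test asserts end to end.

What the generator does **not** emulate: sequencing error and PCR bias,
V(D)J recombination statistics beyond gene-label sampling, realistic
repertoire depths (blood repertoires are thousands, not hundreds of
thousands, of clones), inter-analyte correlations outside the planted
blocks, or covariate structure (age/sex/EDSS are decorative). Passing
tests therefore demonstrate that the *procedures* recover known structure
at study-scale sample sizes — they are not evidence about effect sizes in
real data.

## Monte-Carlo validation sizes

All recovery tests run 200 replicates at the clinical cohort's sample
sizes (24 MS / 9 CTRL). Repertoire depths are scaled to desk size, chosen
by power analysis before freezing: sharing replicates use 2,000 CSF /
3,000 blood clones so the 0.1 % control rate is resolvable (group-mean
SE ≈ 0.024 %); link replicates use 200 CSF / 800 blood clones and a 40k
public pool, which keeps the predominant set small without touching the
planted links; cytokine replicates need no repertoires. The
healthy-reference cohort is omitted where it plays no role (sharing and
link recovery). The full suite runs in a few minutes on one CPU.

## Known limitations

* The Mann–Whitney exact path requires tie-free data; tied small samples
  fall back to the corrected normal approximation.
* Winsorize idempotence is exact only where the tail quantile is attained
  (see above).
* Greedy-modularity sub-clusters are a heuristic stand-in for visually
  drawn cluster boundaries and should be treated as exploratory.
* With very small cohorts (n < 4 per group) the outlier screen and the
  correlation stage skip most cells by design; the pipeline logs every
  such exclusion.
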