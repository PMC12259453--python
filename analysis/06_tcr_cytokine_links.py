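"""Association of MS-predominant TCR sequences with blood cytokines.

Public sequences (>= 2 individuals) are filtered to MS-predominant ones
(>= 5 MS patients and no controls, or >= 10-fold mean clone-proportion
enrichment); each is correlated with every blood cytokine across MS
patients via Kendall's tau-b, BH-adjusted jointly, significant when
adjusted p < 0.05 and |tau| > 0.5.  Tallies are grouped by functional
cytokine category.
"""

import json
import logging

import pandas as pd

from _common import pipeline

logging.basicConfig(level=logging.INFO, format="%(message)s")

run = pipeline()
rec = run.integrate()
print(f"\n{rec['n_public']} public sequences -> {rec['n_predominant']} "
      f"MS-predominant -> {rec['n_significant']} significant associations "
      f"({rec['n_sequences']} sequences x {rec['n_analytes']} cytokines)")
assoc = pd.read_csv(f"{run.cfg.out_dir}/associations.tsv", sep="\t")
sig = assoc[assoc["significant"]].sort_values("adjusted_p")
for row in sig.head(10).itertuples():
    print(f"  {row.cdr3_aa} x {row.analyte} ({row.category}): "
          f"tau = {row.tau:+.2f}, adjusted p = {row.adjusted_p:.2g} [{row.rule}]")
tallies = json.load(open(f"{run.cfg.out_dir}/association_tallies.json"))
print("per-category (positive/negative):",
      {k: (v["positive"], v["negative"]) for k, v in tallies["per_category"].items()})
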