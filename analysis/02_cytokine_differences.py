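"""Cytokine preprocessing and MS-vs-control group comparison.

Per compartment: IQR outlier screen, log2(x+1) transform, 12.5 %
Winsorization, then a Mann–Whitney U test per analyte with BH correction
(fold change = ratio of raw-scale group means).  Writes
results/group_comparison_{CSF,blood}.tsv and the z-scored matrices used
for heatmaps.
"""

import logging

import pandas as pd

from _common import pipeline

logging.basicConfig(level=logging.INFO, format="%(message)s")

run = pipeline()
rec = run.cytokines()
for compartment in ("CSF", "blood"):
    comp = pd.read_csv(f"{run.cfg.out_dir}/group_comparison_{compartment}.tsv",
                       sep="\t", index_col=0)
    sig = comp[comp["significant"]].sort_values("adjusted_p")
    print(f"\n{compartment}: {len(sig)} analyte(s) differ between MS and CTRL "
          f"(BH-adjusted p < 0.05)")
    for analyte, row in sig.iterrows():
        print(f"  {analyte}: {row.fold_change:.2f}-fold, "
              f"adjusted p = {row.adjusted_p:.2g}")
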