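"""Cytokine correlation networks per group and compartment.

Pearson correlations on the preprocessed matrices; an edge requires
|r| >= 0.6 and BH-adjusted p < 0.05.  Connected components are the
network's clusters; a seeded Fruchterman–Reingold layout is exported with
each graph (GraphML + edge TSV + summary JSON).
"""

import json
import logging

from _common import pipeline

logging.basicConfig(level=logging.INFO, format="%(message)s")

run = pipeline()
rec = run.network()
for tag in ("MS_CSF", "MS_blood", "CTRL_CSF", "CTRL_blood"):
    summary = json.load(open(f"{run.cfg.out_dir}/network_{tag}.json"))
    hubs = ", ".join(f"{h['analyte']} ({h['degree']})"
                     for h in summary["top_degree"][:3]) or "none"
    print(f"{tag}: {summary['n_positive']} positive / "
          f"{summary['n_negative']} negative edges, "
          f"{summary['n_isolated']} isolated analytes; hubs: {hubs}")
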