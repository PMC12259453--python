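"""Potentially relevant sequences (PRS) and rank-based k-means clusters.

PRS = CSF sequences that are top-10 by clone count in an MS patient (count
>= 2) or occur in >= 2 MS CSF samples.  Their per-individual count ranks
over MS + healthy-reference individuals are clustered with k-means (k = 2);
the cluster with the higher MS occurrence is the MS-associated cluster.
"""

import logging

from _common import pipeline

logging.basicConfig(level=logging.INFO, format="%(message)s")

run = pipeline()
rec = run.prs()
print(f"\n{rec['n_prs']} PRS ({rec['n_criterion1']} via top-10, "
      f"{rec['n_criterion2']} via multi-patient occurrence), "
      f"clustered over {rec['n_ms_dimensions']} MS + "
      f"{rec['n_healthy_dimensions']} healthy dimensions")
ms = rec["occurrence"]["ms_associated"]
print(f"MS-associated cluster: {ms['n_sequences']} sequences, "
      f"mean occurrence {ms['mean_occurrence_ms']:.1f}% in MS vs "
      f"{ms['mean_occurrence_ref']:.1f}% in healthy "
      f"(Welch p = {ms['welch']['p']:.2g})")
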