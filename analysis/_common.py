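"""Shared configuration for the numbered analysis scripts.

The simulated cohort (raw rearrangement TSVs + panels) lives under
``scratch/cohort`` — it is bulky, regenerable data.  Derived tables and
summaries go to ``results/``.
"""

from pathlib import Path

from tcrcyto.pipeline import PipelineRun, load_config

REPO = Path(__file__).resolve().parent.parent
SEED = 1


def pipeline() -> PipelineRun:
    cfg = load_config(None, seed=SEED,
                      data_dir=str(REPO / "scratch" / "cohort"),
                      out_dir=str(REPO / "results"))
    return PipelineRun(cfg)
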