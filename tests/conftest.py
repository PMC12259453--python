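import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tcrcyto.io_formats import RearrangementTable
from tcrcyto.synthetic_cohort import CohortConfig, generate_cohort


def make_table(sample_id, rows):
    """Build a RearrangementTable from (aa, templates, frame, v_gene) tuples."""
    records = []
    for i, row in enumerate(rows):
        aa, templates = row[0], row[1]
        frame = row[2] if len(row) > 2 else "In"
        v_gene = row[3] if len(row) > 3 else "TRBV9"
        records.append({
            "rearrangement": f"ACGT{i:04d}" + "GGCC" * 8,
            "amino_acid": aa,
            "v_gene": v_gene,
            "d_gene": "TRBD1",
            "j_gene": "TRBJ2-1",
            "templates": templates,
            "frame_type": frame,
        })
    columns = ["rearrangement", "amino_acid", "v_gene", "d_gene", "j_gene",
               "templates", "frame_type"]
    df = pd.DataFrame(records, columns=columns)
    df["templates"] = df["templates"].astype(int)
    return RearrangementTable(sample_id, df)


@pytest.fixture(scope="session")
def small_config():
    """Reduced-depth cohort used by several integration-style tests."""
    return CohortConfig(n_ms=8, n_ctrl=4, n_healthy_ref=6,
                        clones_per_blood=600, clones_per_csf=200, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
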