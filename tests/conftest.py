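import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def toy_reference():
    """Small deterministic reference shared across alignment/classification tests."""
    from kmerdiff import simulate as sim

    return sim.generate_reference(
        n_chromosomes=2,
        chromosome_length=30000,
        n_genes=6,
        exons_per_gene=3,
        seed=123,
    )


@pytest.fixture(scope="session")
def default_cohort_result():
    """One full pipeline run on the default synthetic cohort (session-scoped:
    several acceptance checks share it)."""
    from kmerdiff.pipeline import run_pipeline

    return run_pipeline(seed=11)


def make_sheet(n_tumor, n_normal):
    ids = [f"tumor{i:02d}" for i in range(1, n_tumor + 1)] + [
        f"normal{i:02d}" for i in range(1, n_normal + 1)
    ]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "condition": ["tumor"] * n_tumor + ["normal"] * n_normal,
            "fastq": [""] * (n_tumor + n_normal),
        }
    )


def conditions_of(sheet):
    return pd.Series(sheet["condition"].values, index=sheet["sample_id"].values)
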