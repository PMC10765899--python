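import numpy as np
import pandas as pd
import pytest

import notchsig as ns


@pytest.fixture(scope="session")
def cell_cohort():
    """A mid-sized perturbation experiment shared by read-only tests."""
    cfg = ns.SimulationConfig(seed=101, n_genes=1000, n_responsive=100)
    return ns.generate_cell_line_experiment(cfg)


@pytest.fixture(scope="session")
def patient_cohort():
    """A patient cohort with a 20-gene module of pairwise correlation 0.3."""
    cfg = ns.SimulationConfig(seed=202, n_genes=2000, n_samples=500)
    return ns.generate_patient_cohort(cfg)


@pytest.fixture()
def toy_counts():
    """6 genes x 3 samples of raw counts, no zeros, no ties in M or A."""
    return pd.DataFrame(
        {
            "s1": [100, 250, 37, 1200, 15, 410],
            "s2": [180, 210, 55, 900, 40, 615],
            "s3": [90, 300, 20, 1500, 10, 380],
        },
        index=["GA", "GB", "GC", "GD", "GE", "GF"],
    )


def make_cohort(values: pd.DataFrame, platform: str = "rnaseq_counts", **meta_cols):
    metadata = pd.DataFrame(meta_cols, index=values.columns) if meta_cols else pd.DataFrame(
        index=values.columns
    )
    return ns.ExpressionCohort(values=values, metadata=metadata, platform=platform)


@pytest.fixture()
def make_cohort_fn():
    return make_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
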