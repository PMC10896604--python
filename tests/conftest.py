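import numpy as np
import pandas as pd
import pytest

from rtomics import CohortMetadata, FeatureTable, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted cohort shared across tests (read-only)."""
    cfg = SyntheticConfig(
        n_per_group=12, n_protein_features=200, n_metabolite_features=40,
        frac_differential=0.2, effect_size=2.0, frac_exclusive=0.02,
        missing_rate=0.05, seed=11,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture
def toy_table():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, np.nan, 6.0], [7.0, 8.0, 9.0]],
        index=["f1", "f2", "f3"], columns=["s1", "s2", "s3"],
    )
    return FeatureTable(df, "protein")


@pytest.fixture
def two_group_metadata():
    df = pd.DataFrame(
        {"group": ["GR", "GR", "GR", "PR", "PR", "PR"]},
        index=[f"s{i}" for i in range(6)],
    )
    return CohortMetadata(df)
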