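from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from dermaprofile import CohortTable, FeatureSpec, generate_cohort
from dermaprofile.synthetic import preset

TINY_MANIFEST = [
    FeatureSpec("G1", "genetics", "ordinal", (0, 1, 2)),
    FeatureSpec("L1", "lifestyle", "binary", (0, 1)),
    FeatureSpec("L2", "lifestyle", "ordinal", (0, 1, 2, 3)),
    FeatureSpec("P1", "phenotype", "ordinal", (0, 1, 2)),
]


def tiny_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "G1": [0, 1, 2, 0, 1, 2],
            "L1": [0, 0, 1, 1, 0, 1],
            "L2": [0, 1, 2, 3, 2, 1],
            "P1": [0, 1, 2, 0, 2, 1],
        },
        index=[f"S{i}" for i in range(6)],
    )


@pytest.fixture
def tiny_cohort() -> CohortTable:
    return CohortTable(tiny_frame(), TINY_MANIFEST)


@pytest.fixture(scope="session")
def separable_cohort():
    """Well-separated 4-cluster cohort (n=1000) plus its planted truth."""
    cfg = replace(preset("separable4"), n_subjects=1000, seed=20260928)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
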