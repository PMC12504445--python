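import warnings

import numpy as np
import pandas as pd
import pytest

from strokerisk.schema import (
    PHYSIOLOGICAL_SCHEMA,
    CohortTable,
)
from strokerisk.synth import generate_negative_samples, generate_pathogenic_samples, generate_positive_samples

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def physio_table() -> CohortTable:
    """Mixed-label physiological cohort, 360 negatives / 240 positives."""
    neg = generate_negative_samples(n=360, seed=11)
    pos = generate_positive_samples(n=240, seed=12)
    frame = pd.concat([neg.frame, pos.frame], ignore_index=True)
    return CohortTable(frame, PHYSIOLOGICAL_SCHEMA, "physiological")


@pytest.fixture(scope="session")
def patho_table() -> CohortTable:
    neg = generate_pathogenic_samples(300, 0, seed=13)
    pos = generate_pathogenic_samples(200, 1, seed=14)
    frame = pd.concat([neg.frame, pos.frame], ignore_index=True)
    return CohortTable(frame, neg.schema, "pathogenic")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
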