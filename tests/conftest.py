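import numpy as np
import pandas as pd
import pytest

from braotrial import (
    CohortParams,
    default_normative_profile,
    generate_cohort,
    published_decay_fit,
)

TRUE_Y0, TRUE_PLATEAU, TRUE_K = -9.5, -55.7, 0.01


@pytest.fixture(scope="session")
def normative():
    return default_normative_profile()


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort (17 patients, noise SD 24)."""
    return generate_cohort(CohortParams(seed=7))


@pytest.fixture(scope="session")
def printed_fit():
    """The published decay curve with a residual SD of 24 % attached."""
    return published_decay_fit(sigma=24.0)


def make_records(rows):
    """Small thickness table from (patient, eye, status, day, ring, quadrant,
    layer, thickness) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "eye", "status", "day", "ring", "quadrant",
            "layer", "thickness_um",
        ],
    )


@pytest.fixture
def make_table():
    return make_records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
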