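import numpy as np
import pandas as pd
import pytest

from frailtykit import SimConfig, default_schema, simulate_cohort

# Printed seven-stratum mortality table used across the SSLR tests:
# died/survived counts per frailty-index stratum of an 8,195-subject
# cohort with 1,284 deaths over seven years of follow-up.
TABLE2 = pd.DataFrame(
    {
        "lower": [0.00, 0.03, 0.10, 0.25, 0.30, 0.35, 0.45],
        "upper": [0.03, 0.10, 0.25, 0.30, 0.35, 0.45, 1.00],
        "died": [32, 165, 602, 240, 76, 122, 47],
        "survived": [426, 1547, 3418, 888, 254, 328, 50],
    }
)

TABLE2_SSLR = [0.40, 0.57, 0.95, 1.45, 1.61, 2.00, 5.06]  # stratum 5 recomputed
TABLE2_CI = [
    (0.28, 0.58),
    (0.49, 0.67),
    (0.89, 1.01),
    (1.28, 1.66),
    (1.26, 2.07),
    (1.64, 2.44),
    (3.41, 7.50),
]


@pytest.fixture(scope="session")
def table2_counts() -> pd.DataFrame:
    return TABLE2.copy()


@pytest.fixture(scope="session")
def schema30():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_subjects=2500), seed=20260930)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
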