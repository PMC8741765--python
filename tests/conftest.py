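import numpy as np
import pytest

from tonguedx.cohort import CohortSpec, simulate_cohort
from tonguedx.schema import TongueRecord


@pytest.fixture
def baseline_record() -> TongueRecord:
    """All reference categories, no marks, unlabeled-free baseline."""
    return TongueRecord(
        tongue_body="medium",
        tongue_color="mild_red",
        red_spots=False,
        black_spots=False,
        fissures=False,
        petechiae=False,
        teeth_markings=False,
        fur_color="white",
        saliva="normal",
        fur_thickness="thin",
        label="non_DM",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the published composition (quota mode, seed 1)."""
    return simulate_cohort(CohortSpec(seed=1))


@pytest.fixture
def blob_data():
    """Two tight, well-separated 8-D Gaussian blobs (100/class)."""
    rng = np.random.default_rng(7)
    a = rng.normal(size=(100, 8)) * 0.3
    b = rng.normal(size=(100, 8)) * 0.3
    b[:, 0] += 8.0
    X = np.vstack([a, b])
    y = np.array(["non_DM"] * 100 + ["DM"] * 100, dtype=object)
    return X, y
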