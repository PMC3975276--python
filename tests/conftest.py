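import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from activecommute.accel import CutPointConfig
from activecommute.simulate import CohortConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cutpoints() -> CutPointConfig:
    return CutPointConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-person default-condition cohort shared across tests."""
    cfg = CohortConfig(n_participants=16, seed=11)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def walk_car_cohort():
    """A walkers + drivers cohort (no GPS) for classification and stats tests."""
    cfg = CohortConfig(
        n_participants=40,
        mode_proportions={"walk": 0.7, "car": 0.3},
        seed=23,
        include_gps=False,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


def make_epoch_frame(counts, epoch_s=10, start="2012-05-07 06:00:00", participant_id="P001"):
    """Single-participant epoch frame helper used throughout the suite."""
    n = len(counts)
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) * epoch_s, unit="s")
    return pd.DataFrame(
        {"participant_id": participant_id, "timestamp": ts, "counts": np.asarray(counts, dtype=np.int64)}
    )
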