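import numpy as np
import pandas as pd
import pytest

from funsurf import SimulationConfig, simulate_cohort
from funsurf.cohort import Cohort, SubjectRecord


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition synthetic cohort, small enough for unit tests."""
    cohort, truth = simulate_cohort(SimulationConfig(n_subjects=150, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def marker_arrays(small_cohort):
    """Per-subject (times, values) arrays of the first marker."""
    cohort, _ = small_cohort
    times, values = [], []
    for s in cohort.subjects:
        t, v = s.marker_observations(cohort.marker_names[0])
        times.append(t)
        values.append(v)
    return times, values


def make_subject(sid, meas_rows, pfs=(24.0, False), os_=(30.0, False), baseline=None):
    """Toy SubjectRecord; meas_rows = list of (marker, time, value)."""
    meas = pd.DataFrame(meas_rows, columns=["marker", "time_months", "value"])
    return SubjectRecord(
        subject_id=sid,
        baseline=baseline or {"age": 60.0},
        measurements=meas,
        pfs_time_months=pfs[0],
        pfs_event=pfs[1],
        os_time_months=os_[0],
        os_event=os_[1],
    )


@pytest.fixture
def toy_cohort_factory():
    def factory(subjects, marker_names=("CEA",)):
        return Cohort(list(subjects), marker_names=tuple(marker_names))

    return factory


@pytest.fixture(scope="session")
def toy_survival():
    """6-subject survival data with hand-computable censoring distribution."""
    times = np.array([2.0, 4.0, 5.0, 7.0, 9.0, 11.0])
    events = np.array([True, False, True, False, True, False])
    return times, events
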