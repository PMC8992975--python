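import numpy as np
import pytest
from hypothesis import settings

from batmort.detection import PersistenceTrialSet
from batmort.geometry import SquarePlot

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: persistence-trial check schedule: daily for 4 days, then sparser, 30 d cap
CHECK_DAYS = np.array([1.0, 2.0, 3.0, 4.0, 7.0, 10.0, 14.0, 20.0, 30.0])


@pytest.fixture(scope="session")
def plot() -> SquarePlot:
    return SquarePlot(40.0)


def intervals_from_removals(times, checks=CHECK_DAYS) -> PersistenceTrialSet:
    """Observe exact removal times through a check schedule, producing the
    interval-censored trial set a field crew would record."""
    lo, hi = [], []
    for t in np.asarray(times, float):
        gone = checks[checks >= t]
        if gone.size:
            hi.append(float(gone[0]))
            before = checks[checks < t]
            lo.append(float(before[-1]) if before.size else 0.0)
        else:
            lo.append(float(checks[-1]))
            hi.append(np.inf)
    return PersistenceTrialSet(tuple(lo), tuple(hi))
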