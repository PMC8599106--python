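import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from melcea.markov_engine import CohortTrace, CycleSchedule, WEEKS_PER_MONTH
from melcea.synthetic_data import build_reference_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# The partitioned-survival engine warns whenever extrapolated curves cross;
# the calibrated fixture does this by construction, so keep test output quiet.
logging.getLogger("melcea.markov_engine").setLevel(logging.ERROR)


MONTHLY_SCHEDULE = CycleSchedule(cycle_length_weeks=WEEKS_PER_MONTH)


@pytest.fixture(scope="session")
def reference_fixture():
    return build_reference_fixture()


@pytest.fixture(scope="session")
def reference_traces(reference_fixture):
    return {
        name: reference_fixture.trace(name)
        for name in reference_fixture.strategy_names
    }


def make_trace(
    ned, rpd, cycle_months: float = 1.0, cap_months: float = 12.0
) -> CohortTrace:
    """Build a trace from boundary occupancies (death fills the remainder)."""
    ned = np.asarray(ned, dtype=float)
    rpd = np.asarray(rpd, dtype=float)
    t = np.arange(ned.size) * cycle_months
    on_tx = np.where(t < cap_months - 1e-9, ned, 0.0)
    newly = np.concatenate([[0.0], np.maximum(ned[:-1] - ned[1:], 0.0)])
    return CohortTrace(
        t_start=t,
        ned=ned,
        rpd=rpd,
        death=1.0 - ned - rpd,
        on_treatment=on_tx,
        newly_recurrent=newly,
        cycle_length_months=cycle_months,
    )
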