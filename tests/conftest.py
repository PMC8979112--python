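import numpy as np
import pytest
from hypothesis import settings

import aucpool as ap

settings.register_profile("ci", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("ci")

#: The 12-point clinical collection schedule (hours).
CLINICAL_TIMES = (0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0)
#: Realized per-time-point plasma volumes (μL) for a 480 μL pool.
CLINICAL_VOLUMES = (2.5, 5.0, 7.5, 15.0, 20.0, 20.0, 30.0, 40.0, 40.0, 40.0, 140.0, 120.0)


@pytest.fixture(scope="session")
def clinical_schedule():
    return ap.SamplingSchedule(CLINICAL_TIMES)


@pytest.fixture(scope="session")
def clinical_design(clinical_schedule):
    return ap.pooling_volumes(clinical_schedule, 480.0, rounding_increment=0.1)


def random_profile(rng, times, compound_id="x"):
    values = rng.uniform(0.0, 100.0, size=len(times))
    return ap.ConcentrationProfile(
        compound_id=compound_id,
        times=tuple(times),
        values=tuple(float(v) for v in values),
    )


def random_schedule(rng, max_points=12):
    n = rng.integers(2, max_points + 1)
    times = np.cumsum(rng.uniform(0.05, 5.0, size=n))
    times -= times[0] * rng.integers(0, 2)  # sometimes start at t0 > 0
    times = np.maximum(times, 0.0)
    return ap.SamplingSchedule(times)
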