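import datetime as dt

import numpy as np
import pytest
from shapely.geometry import box

from babblercalls import SimConfig, simulate_dataset
from babblercalls.core_io import CallRecord
from babblercalls.locoh import Territory


def make_calls(points, caller="C1", group="G1"):
    """CallRecords at the given (x, y) points, one per minute."""
    t0 = dt.datetime(2010, 10, 1, 8, 0)
    return [
        CallRecord(caller, group, t0 + dt.timedelta(minutes=k), float(x), float(y), f"s{k}")
        for k, (x, y) in enumerate(points)
    ]


@pytest.fixture(scope="session")
def square_territory():
    """Concentric square isopleths: 100 m (50%), 200 m (75%), 400 m (95%)."""
    isopleths = {
        0.50: box(-50, -50, 50, 50),
        0.75: box(-100, -100, 100, 100),
        0.95: box(-200, -200, 200, 200),
    }
    return Territory(
        group_id="SQ",
        season="test",
        isopleths=isopleths,
        areas_ha={q: g.area / 1e4 for q, g in isopleths.items()},
        a_value=400.0,
        n_fixes=100,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A compact synthetic landscape reused by integration-level tests."""
    return simulate_dataset(SimConfig(n_groups=4, n_fixes_per_group=150, seed=7))


@pytest.fixture(scope="session")
def default_sim():
    """The generator's default study conditions (6 groups, 300 fixes)."""
    return simulate_dataset(SimConfig(seed=1))
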