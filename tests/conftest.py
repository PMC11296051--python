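import numpy as np
import pytest

from pcedetect import (RunConfig, SimConfig, SyncedSeries, prepare_cohort,
                       simulate_cohort)


def series_from_depth_1hz(depth_1hz, rate_hz=25.0, accel=None,
                          label=None, individual_id="test"):
    """Build a SyncedSeries from a 1 Hz depth profile (linear interpolation),
    with zero (or supplied) acceleration."""
    depth_1hz = np.asarray(depth_1hz, dtype=float)
    n1 = len(depth_1hz)
    n25 = int((n1 - 1) * rate_hz)
    t25 = np.arange(n25) / rate_hz
    depth = np.interp(t25, np.arange(n1, dtype=float), depth_1hz)
    if accel is None:
        x = np.zeros(n25)
        y = np.zeros(n25)
        z = np.ones(n25)
    else:
        x, y, z = accel
    return SyncedSeries(t=t25, x=x, y=y, z=z, depth=depth, label=label,
                        individual_id=individual_id, rate_hz=rate_hz)


def brute_force_dives(depth, threshold=0.4):
    """Independent maximal-run scan for depth > threshold."""
    runs = []
    start = None
    for i, d in enumerate(depth):
        if d > threshold and start is None:
            start = i
        elif d <= threshold and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(depth)))
    return runs


@pytest.fixture(scope="session")
def small_cohort():
    """Eight short trips: cheap shared input for module tests."""
    return simulate_cohort(SimConfig(n_individuals=8, trip_duration_s=600,
                                     seed=11))


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    cfg = RunConfig(sim=small_cohort.config, seed=11)
    return prepare_cohort(small_cohort, cfg), cfg
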