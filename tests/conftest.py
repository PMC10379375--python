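"""Shared fixtures: analytic curves and (session-cached) synthetic runs."""

import numpy as np
import pytest
from hypothesis import settings

from timask import RunConfig, SyntheticConfig, TICurve, run_pipeline

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_curve(values, material="m", panelist="p1", replicate=1):
    values = np.asarray(values, dtype=float)
    return TICurve(material, panelist, replicate, np.arange(values.size, dtype=float), values)


def triangle_values(t0=5, peak_t=10, end_t=20, height=40.0, n=23):
    """Piecewise-linear rise t0 -> peak_t, fall peak_t -> end_t, zero outside."""
    t = np.arange(n, dtype=float)
    y = np.zeros(n)
    up = (t >= t0) & (t <= peak_t)
    y[up] = (t[up] - t0) / (peak_t - t0) * height
    down = (t > peak_t) & (t <= end_t)
    y[down] = height * (end_t - t[down]) / (end_t - peak_t)
    return y


@pytest.fixture
def triangle_curve():
    return make_curve(triangle_values())


@pytest.fixture
def trapezoid_curve():
    # ramp 5->10, flat 40 over [10, 14], linear fall to 0 at 22
    t = np.arange(25, dtype=float)
    y = np.zeros(25)
    y[(t >= 5) & (t <= 10)] = (t[(t >= 5) & (t <= 10)] - 5) / 5 * 40
    y[(t > 10) & (t <= 14)] = 40.0
    y[(t > 14) & (t <= 22)] = 40 * (22 - t[(t > 14) & (t <= 22)]) / 8
    return make_curve(y)


@pytest.fixture(scope="session")
def default_run():
    """One full default-scale pipeline run (100 materials), shared read-only."""
    return run_pipeline(RunConfig(seed=1))


#: Narrow-onset design reproducing the strong TsPl/TePl/DurInc collinearity of
#: real panels whose materials all start releasing at nearly the same time:
#: r(TsPl, DurInc) = sd(DurInc)/sqrt(var(DurInc) + var(Tstart)) needs
#: var(Tstart) <= 1.2 s^2 given the ~24 s^2 mixture variance of DurInc.
NARROW_ONSET = {"t_start": (5.5, 6.5), "i_peak": (30.0, 90.0)}


@pytest.fixture(scope="session")
def narrow_onset_run():
    cfg = SyntheticConfig(seed=5, shared_ranges=dict(NARROW_ONSET))
    return run_pipeline(RunConfig(seed=5, synthetic=cfg))


@pytest.fixture
def small_config():
    """A fast small-panel design for I/O and CLI tests."""
    return SyntheticConfig(
        n_essence=3, n_oil=3, n_flavor=4, n_panelists=3, n_replicates=3, seed=11
    )
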