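import numpy as np
import pytest

from ojipcanopy import DEFAULT_GRID, Landmarks, Transient


@pytest.fixture(scope="session")
def grid_times():
    return DEFAULT_GRID.times()


@pytest.fixture()
def ramp_transient(grid_times):
    """F(t) = 100 + 4000 t on the default grid: closed-form line."""
    return Transient("ramp", "N1", "V1", "L1", grid_times, 100.0 + 4000.0 * grid_times)


@pytest.fixture()
def worked_landmarks():
    """The hand-evaluated landmark tuple used throughout the derived-panel tests."""
    return Landmarks(F0=100.0, F300=200.0, FJ=300.0, FI=400.0, FM=500.0, t_fm=0.3, area=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_landmark_tuples(rng, n):
    """Random valid landmark tuples: FM > F0, 0 < VJ < 1, 0 < V300 < VJ."""
    f0 = rng.uniform(100.0, 600.0, n)
    fv = f0 * rng.uniform(0.5, 5.0, n)
    fm = f0 + fv
    vj = rng.uniform(0.05, 0.95, n)
    v300 = vj * rng.uniform(0.05, 0.95, n)
    vi = rng.uniform(0.05, 0.98, n)  # VI < VJ allowed: JI-fall transients
    fj = f0 + vj * fv
    f300 = f0 + v300 * fv
    fi = f0 + vi * fv
    return f0, f300, fj, fi, fm
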