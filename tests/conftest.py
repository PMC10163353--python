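import numpy as np
import pytest

from pivpressure.flow_data import ScalingSet, VelocityFieldSeries
from pivpressure.synthetic_flows import (
    CarangiformParams,
    carangiform_kinematics,
    taylor_green_truth,
)


@pytest.fixture(scope="session")
def tg_small():
    """Taylor-Green truth on a coarse grid (fast unit-test fixture)."""
    x = np.linspace(0.0, 2 * np.pi, 24)
    t = np.linspace(0.0, 0.4, 5)
    vel, pres = taylor_green_truth(x, x, t, Re=100.0)
    return vel, pres


@pytest.fixture(scope="session")
def tg_scaling():
    return ScalingSet(Re=100.0, nu=0.01)


@pytest.fixture(scope="session")
def swimmer_kinematics():
    return carangiform_kinematics(CarangiformParams(), 32,
                                  np.linspace(0.0, 1.0, 11))


@pytest.fixture()
def small_series():
    """Tiny hand-built velocity series (4x4 grid, 3 time steps)."""
    x = np.array([0.0, 0.1, 0.2, 0.3])
    y = np.array([0.0, 0.1, 0.2, 0.3])
    t = np.array([0.0, 0.05, 0.1])
    rng = np.random.default_rng(42)
    u = rng.normal(size=(4, 4, 3))
    v = rng.normal(size=(4, 4, 3))
    return VelocityFieldSeries(x, y, t, u=u, v=v)
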