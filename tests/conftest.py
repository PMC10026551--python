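import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermopid as tp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bench_plant() -> tp.PlantParams:
    """The identified gel + Cu-wire phantom plant."""
    return tp.PlantParams(g=95.83, tau1=2.96, tau2=249.04)


@pytest.fixture(scope="session")
def crit_target() -> tp.ClosedLoopTarget:
    """Critically damped target used for the worked gain synthesis."""
    return tp.closed_loop_target(1.0, 0.2)


@pytest.fixture(scope="session")
def bench_gains(bench_plant, crit_target) -> tp.PIDGains:
    return tp.design_pid(bench_plant, crit_target)


@pytest.fixture(scope="session")
def phantom():
    """Default phantom geometry/materials with a calibrated wire source."""
    geom = tp.PhantomGeometry()
    props = tp.MaterialProps()
    sar = tp.calibrate_sar(geom, props)
    return geom, props, sar


def second_order_step(g, tau1, tau2, u, t):
    """Closed-form step response of g/((tau1 s + 1)(tau2 s + 1))."""
    t = np.asarray(t, dtype=float)
    return g * u * (
        1.0 - (tau2 * np.exp(-t / tau2) - tau1 * np.exp(-t / tau1)) / (tau2 - tau1)
    )
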