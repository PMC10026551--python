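import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import thermopid as tp
from thermopid.control_design import PIDGains
from thermopid.pid_runtime import (
    ControllerConfig,
    ControlState,
    DoseParams,
    actuator_map,
    cem43,
    pid_step,
    rc_limit,
    run_closed_loop,
    safety_gate,
)
from thermopid.signal_chain import NoiseModel
from thermopid.thermal_sim import ThermalModel


def _cfg(gains, **kw):
    defaults = dict(setpoint=25.0, dt=0.1, u_min=0.0, u_max=1.0,
                    mode="normalized")
    defaults.update(kw)
    return ControllerConfig(gains=gains, **defaults)


class TestPIDStep:
    def test_proportional_law(self):
        """A 2 K error through kp = 0.26 commands 0.52 before clamping."""
        gains = PIDGains(kp=0.26, ki=1e-12, kd=0.0, tau_d=1.0)
        cfg = ControllerConfig(gains=gains, setpoint=25.0, dt=0.1)
        state = ControlState(initialized=True)
        new = pid_step(state, 23.0, cfg)
        assert new.u_raw == pytest.approx(0.52, abs=1e-9)

    def test_holds_floor_at_zero_error(self, bench_gains):
        cfg = ControllerConfig(gains=bench_gains, setpoint=25.0, dt=0.1)
        state = ControlState()
        for _ in range(50):
            state = pid_step(state, 25.0, cfg)
        assert state.u == pytest.approx(cfg.u_min, abs=1e-12)

    def test_integral_action_removes_steady_error(self, bench_plant, bench_gains):
        """With integral gain the loop regulates to the set point within
        0.01 K, as the final-value theorem predicts for a type-1 loop."""
        cfg = _cfg(bench_gains, setpoint=25.0)
        res = run_closed_loop(bench_plant, cfg, duration=600.0, baseline=21.1)
        assert abs(res.trace.T_probe_C[-1] - 25.0) < 0.01

    def test_output_always_bounded(self, bench_gains):
        cfg = _cfg(bench_gains)
        state = ControlState()
        rng = np.random.default_rng(0)
        for T in rng.uniform(-50, 150, 200):
            state = pid_step(state, T, cfg)
            assert cfg.u_min <= state.u <= cfg.u_max


class TestActuatorMap:
    @pytest.mark.parametrize("u,expected", [
        (0.25, 4.2),
        (1.25, 9.8),
        (0.0, 0.0),
    ])
    def test_volts_anchors(self, u, expected):
        assert actuator_map(u, mode="volts") == pytest.approx(expected)

    def test_normalized(self):
        assert actuator_map(1.0, mode="normalized") == pytest.approx(9.8)
        assert actuator_map(0.0, mode="normalized") == 0.0

    def test_normalized_domain(self):
        with pytest.raises(ValueError):
            actuator_map(1.5, mode="normalized")


class TestRCLimit:
    def test_worst_case_step_slew_meets_fault_bound(self):
        """The 0.25 -> 1.25 V actuator step through the 0.2 s smoother
        slews at most 5 V/s (equality only in the continuous limit)."""
        dt = 1e-3
        u = np.full(3000, 1.25)
        u[0] = 0.25
        y = rc_limit(u, rc_tau=0.2, dt=dt)
        slew = np.max(np.abs(np.diff(y))) / dt
        assert slew <= 5.0
        assert slew == pytest.approx(5.0, rel=0.01)

    def test_constant_input_converges(self):
        u = np.full(5000, 0.7)
        y = rc_limit(u, rc_tau=0.2, dt=1e-3)
        assert y[-1] == pytest.approx(0.7, abs=1e-9)

    @given(slope=st.floats(0.1, 4.9))
    def test_slow_ramp_slope_never_amplified(self, slope):
        dt = 1e-3
        t = np.arange(0.0, 2.0, dt)
        u = 0.25 + np.clip(slope * t, None, 1.0)
        y = rc_limit(u, rc_tau=0.2, dt=dt)
        assert np.max(np.abs(np.diff(y))) / dt <= slope + 1e-9

    def test_coarse_dt_rejected(self):
        with pytest.raises(ValueError):
            rc_limit(np.ones(10), rc_tau=0.2, dt=0.1)


class TestSafetyGate:
    def test_trips_above_threshold(self):
        u, gated, tripped = safety_gate({"probe": 25.1}, {"probe": 25.0}, 0.8)
        assert u == 0.0 and gated and tripped == ["probe"]

    def test_passes_below_threshold(self):
        u, gated, tripped = safety_gate({"probe": 24.9}, {"probe": 25.0}, 0.8)
        assert u == 0.8 and not gated and tripped == []

    def test_missing_reading_fails_safe(self):
        u, gated, _ = safety_gate({"probe": float("nan")}, {"probe": 25.0}, 0.8)
        assert u == 0.0 and gated
        u, gated, _ = safety_gate({}, {"probe": 25.0}, 0.8)
        assert u == 0.0 and gated

    def test_requires_thresholds(self):
        with pytest.raises(ValueError):
            safety_gate({"probe": 20.0}, {}, 0.5)


class TestCEM43:
    @pytest.mark.parametrize("T,minutes,expected", [
        (43.0, 10.0, 10.0),     # identity at the breakpoint
        (45.0, 15.0, 60.0),     # R=0.5 above: 15 * 4
        (41.0, 10.0, 0.625),    # R=0.25 below: 10 / 16
    ])
    def test_constant_temperature_doses(self, T, minutes, expected):
        n = int(minutes * 600)
        dose = cem43(np.full(n, T), dt_s=0.1)
        assert dose == pytest.approx(expected, rel=1e-9)

    @given(split=st.integers(10, 590))
    def test_additivity_over_concatenation(self, split):
        rng = np.random.default_rng(1)
        temps = rng.uniform(37.0, 46.0, 600)
        whole = cem43(temps, dt_s=0.1)
        parts = cem43(temps[:split], dt_s=0.1) + cem43(temps[split:], dt_s=0.1)
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_monotone_accumulation_in_loop(self, bench_plant, bench_gains):
        cfg = _cfg(bench_gains, setpoint=45.0)
        res = run_closed_loop(bench_plant, cfg, duration=120.0, baseline=37.0)
        assert np.all(np.diff(res.trace.cem43_min) >= 0)


class TestClosedLoop:
    def test_meets_transient_requirements(self, bench_plant, bench_gains):
        """The tuned loop on the phantom plant meets the treatment
        transient requirements: settles into +/-0.5 K inside 5 min with
        overshoot below 5%."""
        cfg = _cfg(bench_gains, setpoint=25.1)
        res = run_closed_loop(bench_plant, cfg, duration=600.0, baseline=21.1)
        assert res.metrics["tss"] < 300.0
        assert res.metrics["mp"] < 0.05
        assert res.metrics["ess"] < 0.05

    def test_negligible_gains_stay_at_baseline(self, bench_plant):
        gains = PIDGains(kp=1e-12, ki=1e-12, kd=0.0, tau_d=1.0)
        cfg = _cfg(gains, setpoint=45.0)
        res = run_closed_loop(bench_plant, cfg, duration=60.0, baseline=37.0)
        assert np.all(np.abs(res.trace.T_probe_C - 37.0) < 1e-6)

    def test_antiwindup_limits_post_saturation_overshoot(
            self, bench_plant, bench_gains):
        """After a long saturated rise the loop recovers without a
        secondary overshoot beyond 1% of the step over the critically
        damped (overshoot-free) design."""
        cfg = _cfg(bench_gains, setpoint=45.0)
        res = run_closed_loop(bench_plant, cfg, duration=900.0, baseline=37.0)
        assert res.metrics["mp"] <= 0.01

    def test_safety_dominance_under_adversarial_threshold(
            self, bench_plant, bench_gains):
        """Threshold below the set point: the loop degenerates to relay
        action, and at every logged gated step the commanded field is
        exactly zero."""
        cfg = _cfg(bench_gains, setpoint=30.0, thresholds={"probe": 25.0})
        res = run_closed_loop(bench_plant, cfg, duration=600.0, baseline=21.1)
        trace = res.trace
        gated = trace.gated > 0.5
        assert gated.any()
        assert np.all(trace.H_kA_per_m[gated] == 0.0)
        assert np.all(trace.u_V[gated] == 0.0)
        # relay behavior: alternating events per probe, bounded excursion
        actions = [e.action for e in res.events]
        assert len(actions) >= 4
        assert all(a != b for a, b in zip(actions, actions[1:]))
        assert trace.T_probe_C.max() < 25.0 + 2.0

    def test_noise_model_requires_seed(self, bench_plant, bench_gains):
        cfg = _cfg(bench_gains)
        with pytest.raises(ValueError, match="seed"):
            run_closed_loop(bench_plant, cfg, duration=10.0,
                            noise_model=NoiseModel(), baseline=21.1)

    def test_noisy_run_reproducible(self, bench_plant, bench_gains):
        cfg = _cfg(bench_gains)
        kw = dict(duration=30.0, baseline=21.1,
                  noise_model=NoiseModel(), seed=11)
        a = run_closed_loop(bench_plant, cfg, **kw)
        b = run_closed_loop(bench_plant, cfg, **kw)
        np.testing.assert_array_equal(a.trace.T_probe_C, b.trace.T_probe_C)
        np.testing.assert_array_equal(a.trace.u_V, b.trace.u_V)

    def test_thermal_plant_closed_loop_regulates(self, phantom, bench_gains):
        """The loop closed around the finite-difference phantom (rather
        than the identified transfer function) still regulates to the
        25 C verification set point."""
        geom, props, sar = phantom
        model = ThermalModel(geom, props, sar)
        cfg = _cfg(bench_gains, setpoint=25.0, dt=0.5,
                   thresholds={"probe": 30.0})
        res = run_closed_loop(model, cfg, duration=600.0)
        assert abs(res.trace.T_probe_C[-1] - 25.0) < 0.1
        assert res.trace.T_probe_C.max() < 25.0 + 0.25 * (25.0 - props.T_inf)
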