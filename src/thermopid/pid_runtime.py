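"""Discrete closed-loop execution: PID, saturation, rate limit, safety.

Each 100 ms control interval proceeds in a fixed order: read the
(optionally noisy, filtered) probe temperature -> safety gate -> PID
update -> RC rate limit -> actuator (volts -> field amplitude) -> plant
advance -> thermal-dose update.  The safety gate has strict priority
over the PID law: whenever any monitored probe exceeds its threshold
the commanded output is forced to zero within one control step, and
the PID resumes once all probes are back below threshold.

Thermal dose is accumulated as CEM43 (cumulative equivalent minutes at
43 deg C) with the Sapareto-Dewey convention R = 0.5 above the 43 deg C
breakpoint and R = 0.25 below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import expm

from .control_design import PIDGains, PlantParams, transient_metrics
from .trace import TemperatureTrace

__all__ = [
    "ControllerConfig",
    "ControlState",
    "DoseParams",
    "SafetyEvent",
    "ClosedLoopResult",
    "pid_step",
    "actuator_map",
    "rc_limit",
    "safety_gate",
    "cem43",
    "run_closed_loop",
    "LTIPlant",
]

# linear volt -> field anchors of the power supply
U_LO_V, H_LO = 0.25, 4.2     # V -> kA/m
U_HI_V, H_HI = 1.25, 9.8


@dataclass(frozen=True)
class ControllerConfig:
    """Closed-loop controller settings.

    setpoint in deg C; dt is the control interval (100 ms); u bounds in
    the controller's output units (volts mode: the 0.25-1.25 V supply
    window; normalized mode: [0, 1]); thresholds maps probe ids to
    safety cutoff temperatures; rc_tau is the output smoother time
    constant and dvdt_max the supply's fault bound.
    """

    gains: PIDGains
    setpoint: float
    dt: float = 0.1
    u_min: float = 0.25
    u_max: float = 1.25
    thresholds: Mapping[str, float] = field(default_factory=dict)
    rc_tau: Optional[float] = 0.2  # None disables output smoothing
    dvdt_max: float = 5.0
    mode: str = "volts"  # 'volts' or 'normalized'

    def __post_init__(self) -> None:
        if self.u_min >= self.u_max:
            raise ValueError("u_min must be below u_max")
        if self.dt <= 0 or (self.rc_tau is not None and self.rc_tau <= 0):
            raise ValueError("dt and rc_tau must be positive")
        if self.mode not in ("volts", "normalized"):
            raise ValueError("mode must be 'volts' or 'normalized'")


@dataclass
class ControlState:
    """Mutable PID state carried between control steps."""

    integral: float = 0.0          # K s accumulator
    prev_error: float = 0.0
    filtered_derivative: float = 0.0  # K/s
    u: float = 0.0                 # commanded output (pre rate limit)
    u_raw: float = 0.0             # unclamped PID output
    gated: bool = False
    initialized: bool = False


@dataclass(frozen=True)
class DoseParams:
    """CEM43 isoeffect-dose constants (Sapareto-Dewey)."""

    r_above: float = 0.5
    r_below: float = 0.25
    breakpoint: float = 43.0


@dataclass(frozen=True)
class SafetyEvent:
    time_s: float
    probe: str
    temperature: float
    action: str  # 'gate_on' | 'gate_off'


@dataclass
class ClosedLoopResult:
    trace: TemperatureTrace
    events: list[SafetyEvent]
    cem43_min: float
    metrics: dict


# ---------------------------------------------------------------------------
# PID law
# ---------------------------------------------------------------------------

def pid_step(state: ControlState, T_meas: float, cfg: ControllerConfig) -> ControlState:
    """One backward-Euler PID update; returns the new state.

    Anti-windup: the integral is frozen whenever the unclamped output
    saturates in the same direction as the error pushes.  The
    derivative acts on the error through a first-order filter with the
    design constant tau_d.  Output is clamped to [u_min, u_max].
    """
    g = cfg.gains
    e = cfg.setpoint - T_meas
    if not state.initialized:
        # bumpless start: integral preloaded so u(0) = u_min at zero error
        # (no preload when the floor is at or below zero); prev_error
        # starts at 0 so a reference step produces the derivative kick
        state = replace_state(state, integral=max(cfg.u_min, 0.0) / g.ki,
                              initialized=True)
    # filtered derivative (backward Euler on tau_d df/dt + df = de/dt)
    d_f = (g.tau_d * state.filtered_derivative + (e - state.prev_error)) / (
        g.tau_d + cfg.dt
    )
    integral_candidate = state.integral + e * cfg.dt
    u_raw = g.kp * e + g.ki * integral_candidate + g.kd * d_f
    if (u_raw > cfg.u_max and e > 0) or (u_raw < cfg.u_min and e < 0):
        integral = state.integral  # clamp: freeze integration while saturated
        u_raw = g.kp * e + g.ki * integral + g.kd * d_f
    else:
        integral = integral_candidate
    u = min(max(u_raw, cfg.u_min), cfg.u_max)
    return ControlState(
        integral=integral,
        prev_error=e,
        filtered_derivative=d_f,
        u=u,
        u_raw=u_raw,
        gated=state.gated,
        initialized=True,
    )


def replace_state(state: ControlState, **kw) -> ControlState:
    d = state.__dict__ | kw
    return ControlState(**d)


# ---------------------------------------------------------------------------
# Actuator chain
# ---------------------------------------------------------------------------

def actuator_map(u: float, H_max: float = 9.8, mode: str = "volts") -> float:
    """Map controller output to field amplitude H in kA/m.

    volts mode: linear through the supply anchors (0.25 V -> 4.2 kA/m,
    1.25 V -> 9.8 kA/m) over the working range, falling linearly to
    H = 0 at 0 V below the lower anchor (a gated 0 V command yields
    zero field).  normalized mode: H = u * H_max with u in [0, 1].
    """
    if mode == "normalized":
        if not -1e-12 <= u <= 1.0 + 1e-12:
            raise ValueError("normalized u must lie in [0, 1]")
        return max(0.0, u) * H_max
    if u <= 0.0:
        return 0.0
    if u < U_LO_V:
        return u / U_LO_V * H_LO
    slope = (H_HI - H_LO) / (U_HI_V - U_LO_V)
    return min(H_LO + slope * (u - U_LO_V), H_max)


def rc_limit(u_series: np.ndarray, rc_tau: float, dt: float) -> np.ndarray:
    """First-order RC smoothing of a command series (exact per step).

    y[k] = a y[k-1] + (1-a) u[k], a = exp(-dt/tau): the zero-order-hold
    exact response of y' = (u - y)/tau.  The output slew never exceeds
    (max step)/tau, which keeps the supply's dV/dt fault bound.
    """
    u_series = np.asarray(u_series, dtype=float)
    if dt >= rc_tau / 2:
        raise ValueError("dt must be below rc_tau/2 to resolve the smoother")
    a = math.exp(-dt / rc_tau)
    y = np.empty_like(u_series)
    y[0] = u_series[0]
    for k in range(1, u_series.size):
        y[k] = a * y[k - 1] + (1.0 - a) * u_series[k]
    return y


def safety_gate(
    T_probes: Mapping[str, Optional[float]],
    thresholds: Mapping[str, float],
    u: float,
) -> tuple[float, bool, list[str]]:
    """Force u to zero when any probe exceeds its threshold.

    Returns (u_out, gated, tripped probe ids).  A missing or non-finite
    probe reading closes the gate (fail-safe).
    """
    if not thresholds:
        raise ValueError("at least one safety threshold must be configured")
    tripped: list[str] = []
    for probe, limit in thresholds.items():
        reading = T_probes.get(probe)
        if reading is None or not math.isfinite(reading):
            tripped.append(probe)
        elif reading > limit:
            tripped.append(probe)
    if tripped:
        return 0.0, True, tripped
    return u, False, []


def cem43(
    trace: TemperatureTrace | np.ndarray,
    dose: DoseParams = DoseParams(),
    dt_s: Optional[float] = None,
) -> float:
    """Cumulative equivalent minutes at 43 deg C over a trace.

    CEM43 = sum over samples of (dt/60) * R^(43 - T_i) with R = 0.5 for
    T >= 43 and R = 0.25 below.
    """
    if isinstance(trace, TemperatureTrace):
        temps = trace.T_probe_C
        dt_s = trace.dt
    else:
        temps = np.asarray(trace, dtype=float)
        if dt_s is None:
            raise ValueError("dt_s required for a bare temperature array")
    R = np.where(temps >= dose.breakpoint, dose.r_above, dose.r_below)
    return float(np.sum((dt_s / 60.0) * R ** (dose.breakpoint - temps)))


# ---------------------------------------------------------------------------
# Plant wrappers
# ---------------------------------------------------------------------------

class LTIPlant:
    """Exact ZOH discretization of g / ((tau1 s + 1)(tau2 s + 1)).

    Temperature is baseline + y where y responds to the control input
    held constant over each dt interval.
    """

    def __init__(self, params: PlantParams, dt: float, baseline: float) -> None:
        self.params = params
        self.baseline = baseline
        A = np.array([
            [-1.0 / params.tau1, 0.0],
            [params.g / params.tau2, -1.0 / params.tau2],
        ])
        B = np.array([[1.0 / params.tau1], [0.0]])
        # ZOH: [Ad Bd; 0 I] = expm([[A B],[0 0]] dt)
        M = np.zeros((3, 3))
        M[:2, :2] = A
        M[:2, 2:] = B
        Md = expm(M * dt)
        self.Ad = Md[:2, :2]
        self.Bd = Md[:2, 2:]
        self.x = np.zeros((2, 1))

    def advance(self, u: float) -> float:
        self.x = self.Ad @ self.x + self.Bd * u
        return self.baseline + float(self.x[1, 0])

    def readings(self, T: float) -> dict[str, float]:
        return {"probe": T}


class _ThermalPlantAdapter:
    """Drives a ThermalModel one control step at a time."""

    def __init__(self, model, dt: float) -> None:
        self.model = model
        self.dt = dt
        self.T_grid = model.initial_state()

    @property
    def baseline(self) -> float:
        return self.model.props.T_inf

    def advance(self, H_kam: float) -> float:
        self.T_grid = self.model.step(self.T_grid, H_kam, self.dt)
        return self.model.probe_temperature(self.T_grid)

    def readings(self, T: float) -> dict[str, float]:
        return {"probe": T}


# ---------------------------------------------------------------------------
# Closed loop
# ---------------------------------------------------------------------------

def run_closed_loop(
    plant,
    cfg: ControllerConfig,
    duration: float,
    noise_model=None,
    seed: Optional[int] = None,
    baseline: Optional[float] = None,
    dose: DoseParams = DoseParams(),
    H_max: float = 9.8,
) -> ClosedLoopResult:
    """Execute the discrete loop against an LTI plant or thermal model.

    ``plant`` may be a PlantParams (LTI mode: the control input drives
    the transfer function directly) or a thermal_sim.ThermalModel (the
    commanded voltage is mapped to field amplitude through the actuator
    anchors).  With a signal_chain.NoiseModel attached, each control
    interval reads a block-averaged, Butterworth-filtered noisy sensor
    block; a seed is then mandatory.
    """
    from .control_design import PlantParams as _PP  # local to avoid cycles

    if noise_model is not None and seed is None:
        raise ValueError("a seed is required when a noise model is attached")

    if isinstance(plant, _PP):
        sim = LTIPlant(plant, cfg.dt, baseline if baseline is not None else 0.0)
        lti_mode = True
    else:
        sim = _ThermalPlantAdapter(plant, cfg.dt)
        lti_mode = False

    sensor = None
    if noise_model is not None:
        from .signal_chain import OnlineSensorChain
        sensor = OnlineSensorChain(noise_model, cfg.dt, seed=seed)

    n = int(round(duration / cfg.dt))
    state = ControlState()
    thresholds = dict(cfg.thresholds) or {"probe": math.inf}
    events: list[SafetyEvent] = []
    gate_closed = {p: False for p in thresholds}

    times = np.arange(n + 1) * cfg.dt
    T_log = np.empty(n + 1)
    u_log = np.zeros(n + 1)
    H_log = np.zeros(n + 1)
    gated_log = np.zeros(n + 1)
    dose_log = np.zeros(n + 1)

    T_true = sim.baseline
    T_log[0] = T_true
    u_smooth = cfg.u_min if cfg.mode == "volts" else 0.0
    u_log[0] = u_smooth
    a_rc = math.exp(-cfg.dt / cfg.rc_tau) if cfg.rc_tau is not None else 0.0
    dose_acc = 0.0

    for k in range(1, n + 1):
        # 1. sense
        T_meas = sensor.read(T_true) if sensor is not None else T_true
        readings = sim.readings(T_meas)
        # 2. safety gate (strict priority over PID)
        _, gated, tripped = safety_gate(readings, thresholds, 1.0)
        for p in thresholds:
            now = p in tripped
            if now != gate_closed[p]:
                events.append(SafetyEvent(
                    time_s=times[k], probe=p,
                    temperature=readings.get(p, math.nan),
                    action="gate_on" if now else "gate_off",
                ))
                gate_closed[p] = now
        # 3. control
        if gated:
            u_cmd = 0.0
            state = replace_state(state, gated=True,
                                  prev_error=cfg.setpoint - T_meas)
        else:
            state = pid_step(replace_state(state, gated=False), T_meas, cfg)
            u_cmd = state.u
        # 4. RC rate limit (exact first-order smoothing); the safety
        # gate overrides the smoother so the field reaches zero within
        # one control step (the supply's power-down path)
        if gated:
            u_smooth = 0.0
        else:
            u_smooth = a_rc * u_smooth + (1.0 - a_rc) * u_cmd
        # 5. actuate and 6. advance plant
        if lti_mode:
            T_true = sim.advance(u_smooth)
            H = actuator_map(u_smooth, H_max=H_max, mode=cfg.mode) \
                if cfg.mode == "volts" else u_smooth * H_max
        else:
            H = actuator_map(u_smooth, H_max=H_max, mode=cfg.mode)
            T_true = sim.advance(H)
        # 7. dose update
        dp = dose
        R = dp.r_above if T_true >= dp.breakpoint else dp.r_below
        dose_acc += (cfg.dt / 60.0) * R ** (dp.breakpoint - T_true)

        T_log[k] = T_true
        u_log[k] = u_smooth
        H_log[k] = H
        gated_log[k] = 1.0 if gated else 0.0
        dose_log[k] = dose_acc

    trace = TemperatureTrace(
        time_s=times, T_probe_C=T_log, u_V=u_log, H_kA_per_m=H_log,
        gated=gated_log, cem43_min=dose_log,
    )
    try:
        metrics = transient_metrics(trace, cfg.setpoint)
    except ValueError:
        metrics = {}
    return ClosedLoopResult(
        trace=trace, events=events, cem43_min=dose_acc, metrics=metrics
    )
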