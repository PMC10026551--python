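"""Pole-placement PID design from transient specifications.

The closed loop is shaped to a canonical second-order target

    Q(s) = wn^2 / (s^2 + 2 zeta wn s + wn^2)

whose poles -sigma +/- j wd (sigma = zeta wn, wd = wn sqrt(1-zeta^2))
must lie in the s-plane region implied by the user's rise-time,
settling-time and overshoot requirements.  Given an identified
two-time-constant plant

    P(s) = g / ((tau1 s + 1)(tau2 s + 1))

the controller C(s) = Q / ((1 - Q) P) reduces exactly to a PID with a
first-order derivative filter, which fixes the gains in closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .trace import TemperatureTrace

__all__ = [
    "TransientSpec",
    "PoleRegion",
    "ClosedLoopTarget",
    "PlantParams",
    "PIDGains",
    "spec_to_pole_region",
    "overshoot_from_zeta",
    "zeta_for_overshoot",
    "closed_loop_target",
    "design_pid",
    "simulate_reference_response",
    "transient_metrics",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransientSpec:
    """Transient performance requirements for the closed loop.

    tr_max: maximum 10-90% rise time (s); tss_max: maximum settling time
    into +/- settle_band (s); mp_max: maximum fractional overshoot in
    (0, 1); settle_band: settling band half-width (K); treatment_window:
    (min, max) required hold duration at set point (s).
    """

    tr_max: float = 60.0
    tss_max: float = 300.0
    mp_max: float = 0.05
    settle_band: float = 0.5
    treatment_window: tuple[float, float] = (900.0, 1800.0)

    def __post_init__(self) -> None:
        if not (self.tr_max > 0 and self.tss_max > 0 and self.settle_band > 0):
            raise ValueError("tr_max, tss_max and settle_band must be positive")
        if not 0.0 < self.mp_max < 1.0:
            raise ValueError("mp_max must lie in (0, 1)")
        lo, hi = self.treatment_window
        if not 0 < lo <= hi:
            raise ValueError("treatment_window must be ordered and positive")


@dataclass(frozen=True)
class PoleRegion:
    """Admissible s-plane region for the closed-loop poles."""

    omega_n_min: float
    sigma_min: float
    zeta_min: float
    zeta_max: float = 1.0

    def __post_init__(self) -> None:
        if self.omega_n_min <= 0 or self.sigma_min <= 0:
            raise ValueError("omega_n_min and sigma_min must be positive")
        if not 0.0 < self.zeta_min < self.zeta_max <= 1.0:
            raise ValueError("require 0 < zeta_min < zeta_max <= 1")

    def contains(self, zeta: float, omega_n: float) -> bool:
        return (
            omega_n >= self.omega_n_min
            and zeta * omega_n >= self.sigma_min
            and self.zeta_min <= zeta <= self.zeta_max
        )


@dataclass(frozen=True)
class ClosedLoopTarget:
    """Chosen pole pair of the target second-order closed loop."""

    zeta: float
    omega_n: float
    sigma: float
    omega_d: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError("zeta must lie in [0, 1]")
        if self.omega_n <= 0:
            raise ValueError("omega_n must be positive")
        scale = max(self.omega_n, 1e-300)
        if abs(self.sigma - self.zeta * self.omega_n) > 1e-12 * scale:
            raise ValueError("sigma inconsistent with zeta * omega_n")
        wd = self.omega_n * math.sqrt(max(0.0, 1.0 - self.zeta**2))
        if abs(self.omega_d - wd) > 1e-12 * scale:
            raise ValueError("omega_d inconsistent with omega_n, zeta")


@dataclass(frozen=True)
class PlantParams:
    """Two-time-constant plant P(s) = g / ((tau1 s + 1)(tau2 s + 1)).

    g: static gain (K per unit control input); tau1 < tau2 in seconds.
    tau63 = tau1 + tau2 approximates the time to 63% of the step gain.
    """

    g: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("static gain g must be positive")
        if not 0.0 < self.tau1 < self.tau2:
            raise ValueError("require 0 < tau1 < tau2")

    @property
    def tau63(self) -> float:
        return self.tau1 + self.tau2


@dataclass(frozen=True)
class PIDGains:
    """PID gains with first-order derivative filter constant tau_d.

    C(s) = kp + ki/s + kd s / (1 + tau_d s);  kappa = ki is the common
    scale factor omega_n / (2 zeta g).
    """

    kp: float
    ki: float
    kd: float
    tau_d: float

    def __post_init__(self) -> None:
        if self.kp <= 0 or self.ki <= 0 or self.tau_d <= 0:
            raise ValueError("kp, ki and tau_d must be positive")
        if self.kd < 0:
            raise ValueError("kd must be non-negative")

    @property
    def kappa(self) -> float:
        return self.ki


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def overshoot_from_zeta(zeta: float) -> float:
    """Fractional peak overshoot of the second-order step response.

    Mp(zeta) = exp(-pi zeta / sqrt(1 - zeta^2)); Mp(0) = 1, Mp(1) = 0
    (limit).
    """
    if not 0.0 <= zeta <= 1.0:
        raise ValueError("zeta must lie in [0, 1]")
    if zeta >= 1.0:
        return 0.0
    return math.exp(-math.pi * zeta / math.sqrt(1.0 - zeta**2))


def zeta_for_overshoot(mp: float, tol: float = 1e-10) -> float:
    """Invert Mp(zeta) = mp by bisection on [0, 1 - 1e-9].

    Deterministic; the returned root satisfies |Mp(zeta) - mp| < tol.
    """
    if not 0.0 < mp < 1.0:
        raise ValueError("overshoot fraction must lie in (0, 1)")
    lo, hi = 0.0, 1.0 - 1e-9
    # Mp is strictly decreasing in zeta.
    while True:
        mid = 0.5 * (lo + hi)
        val = overshoot_from_zeta(mid)
        if abs(val - mp) < tol or hi - lo < 1e-15:
            return mid
        if val > mp:
            lo = mid
        else:
            hi = mid


def spec_to_pole_region(spec: TransientSpec) -> PoleRegion:
    """Translate transient requirements into s-plane pole constraints.

    Uses the standard second-order rules tr ~ 1.8/omega_n (10-90% rise)
    and tss ~ 4.6/sigma (1% settling), plus the exact overshoot formula
    for the damping-ratio bound.
    """
    return PoleRegion(
        omega_n_min=1.8 / spec.tr_max,
        sigma_min=4.6 / spec.tss_max,
        zeta_min=zeta_for_overshoot(spec.mp_max),
        zeta_max=1.0,
    )


def closed_loop_target(zeta: float, omega_n: float) -> ClosedLoopTarget:
    """Build the target pole pair from (zeta, omega_n)."""
    if not 0.0 <= zeta <= 1.0:
        raise ValueError("zeta must lie in [0, 1]")
    if omega_n <= 0:
        raise ValueError("omega_n must be positive")
    return ClosedLoopTarget(
        zeta=zeta,
        omega_n=omega_n,
        sigma=zeta * omega_n,
        omega_d=omega_n * math.sqrt(max(0.0, 1.0 - zeta**2)),
    )


def design_pid(plant: PlantParams, target: ClosedLoopTarget) -> PIDGains:
    """Synthesize PID gains so the closed loop equals the target Q(s).

    With tau_d = 1/(2 zeta omega_n) and kappa = omega_n/(2 zeta g):

        kp = kappa (tau1 + tau2 - tau_d)
        ki = kappa
        kd = kappa (tau1 - tau_d)(tau2 - tau_d)

    kd is floored at zero when tau1 < tau_d: the algebra then calls for
    a negative derivative gain, which is destabilizing in practice.
    """
    if target.zeta <= 0:
        raise ZeroDivisionError("zeta = 0 gives an unbounded derivative filter")
    tau_d = 1.0 / (2.0 * target.zeta * target.omega_n)
    kappa = target.omega_n / (2.0 * target.zeta * plant.g)
    kp = kappa * (plant.tau1 + plant.tau2 - tau_d)
    kd = kappa * (plant.tau1 - tau_d) * (plant.tau2 - tau_d)
    if kd < 0.0:
        warnings.warn(
            "derivative gain clipped to 0 (tau1 < tau_d); the plant is "
            "faster than the derivative filter",
            stacklevel=2,
        )
        kd = 0.0
    return PIDGains(kp=kp, ki=kappa, kd=kd, tau_d=tau_d)


def simulate_reference_response(
    target: ClosedLoopTarget,
    step: float,
    duration: float,
    dt: float,
    baseline: float = 0.0,
) -> TemperatureTrace:
    """Analytic step response of the target closed loop Q(s).

    Serves as the oracle for closed-loop equivalence checks.  Returns
    baseline + step * q(t) sampled every dt, where q is the unit step
    response (unit DC gain).
    """
    if dt >= 0.1 / target.omega_n:
        raise ValueError("dt must resolve the target dynamics (dt < 0.1/omega_n)")
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    z, wn = target.zeta, target.omega_n
    if z >= 1.0:
        q = 1.0 - (1.0 + wn * t) * np.exp(-wn * t)
    elif z <= 0.0:
        q = 1.0 - np.cos(wn * t)
    else:
        wd = target.omega_d
        sig = target.sigma
        q = 1.0 - np.exp(-sig * t) * (np.cos(wd * t) + (sig / wd) * np.sin(wd * t))
    return TemperatureTrace(time_s=t, T_probe_C=baseline + step * q)


def transient_metrics(
    trace: TemperatureTrace,
    setpoint: float,
    band: float = 0.5,
) -> dict:
    """Rise time, overshoot, settling time and steady error of a trace.

    tr: 10%->90% rise time of the normalized response (linear
    interpolation between samples); None with a warning if 90% is never
    reached.  mp: (Tmax - setpoint)/(setpoint - T0), floored at 0.
    tss: first time after which |T - setpoint| <= band for the rest of
    the trace.  ess: mean |T - setpoint| over the final 10%.
    """
    t = trace.time_s - trace.time_s[0]
    temp = trace.T_probe_C
    t0_val = temp[0]
    step = setpoint - t0_val
    if step <= 0:
        raise ValueError("setpoint must exceed the initial temperature")
    y = (temp - t0_val) / step

    def _crossing(level: float) -> Optional[float]:
        above = y >= level
        if not above.any():
            return None
        i = int(np.argmax(above))
        if i == 0:
            return float(t[0])
        # linear interpolation between samples i-1 and i
        frac = (level - y[i - 1]) / (y[i] - y[i - 1])
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))

    t10 = _crossing(0.1)
    t90 = _crossing(0.9)
    if t90 is None or t10 is None:
        warnings.warn("trace never reaches 90% of the step; rise time undefined")
        tr = None
    else:
        tr = t90 - t10

    mp = max(0.0, (float(temp.max()) - setpoint) / step)

    inside = np.abs(temp - setpoint) <= band
    # first index from which all later samples stay inside the band
    stays = np.logical_and.accumulate(inside[::-1])[::-1]
    if stays[-1]:
        i = int(np.argmax(stays))
        tss = float(t[i]) if not stays.all() else 0.0
    else:
        tss = None

    tail = temp[int(0.9 * len(temp)):]
    ess = float(np.mean(np.abs(tail - setpoint)))
    return {"tr": tr, "mp": mp, "tss": tss, "ess": ess}
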