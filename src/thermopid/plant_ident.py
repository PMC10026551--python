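"""Open-loop plant identification for the gel + wire phantom.

The phantom behaves as an overdamped second-order system
P(s) = g / ((tau1 s + 1)(tau2 s + 1)).  Three complementary readings
are taken from a step (or pulse) response:

* the static gain g = dT_saturation / u_step;
* the classic graphical readings — the time of maximum heating rate
  ("inflection delay") and the 63%-of-gain crossing time tau63 — which
  give quick first estimates of the fast and combined time constants;
* a two-exponential least-squares fit of the full step-response shape,
  initialized from the graphical readings, which is the authoritative
  estimator (the inflection delay only approximates tau1 and is biased
  whenever tau1 is not infinitesimally fast).

The undamped natural frequency is read off a proportional-only closed
loop by peak spacing of the decaying oscillation, omega_n = 2 pi / T.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .control_design import PlantParams
from .trace import TemperatureTrace

__all__ = [
    "StepResponseTrace",
    "IdentificationResult",
    "static_gain",
    "identify_time_constants",
    "natural_frequency_from_period",
    "estimate_period_from_oscillation",
]


class IdentificationError(RuntimeError):
    pass


@dataclass
class StepResponseTrace:
    """Temperature response to a step of magnitude u_step at step_time."""

    times: np.ndarray
    temperatures: np.ndarray
    u_step: float
    step_time: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.u_step <= 0:
            raise ValueError("u_step must be positive")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.abs(steps - steps[0]) > 1e-9 * max(steps[0], 1.0)):
            raise ValueError("times must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class IdentificationResult:
    """Identified plant plus diagnostics.

    method: 'two-exponential fit' or 'inflection' (whichever produced
    ``plant``); the graphical readings are always reported alongside.
    """

    plant: PlantParams
    method: str
    residual_rms: float
    tau1_inflection: float
    tau63: float

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")


def static_gain(delta_T: float, u_step: float) -> float:
    """Static gain g = dT / u_step in K per input unit."""
    if u_step == 0:
        raise ValueError("u_step must be non-zero")
    return delta_T / u_step


def _step_shape(t: np.ndarray, dT: float, tau1: float, tau2: float) -> np.ndarray:
    """Unit-step response of g/((tau1 s+1)(tau2 s+1)) scaled to dT."""
    if abs(tau2 - tau1) < 1e-9 * tau2:
        # repeated-pole limit
        return dT * (1.0 - (1.0 + t / tau2) * np.exp(-t / tau2))
    return dT * (
        1.0
        - (tau2 * np.exp(-t / tau2) - tau1 * np.exp(-t / tau1)) / (tau2 - tau1)
    )


def identify_time_constants(
    trace: StepResponseTrace,
    asymptote: float | None = None,
    fit_tolerance_rms: float = 0.0,
) -> IdentificationResult:
    """Estimate (g, tau1, tau2) from a heating step response.

    The graphical readings (inflection delay, 63% crossing) seed a
    two-exponential least-squares fit.  The fit result is returned as
    ``plant`` unless its residual is worse than the graphical one;
    ``fit_tolerance_rms`` (K) lets callers force the fallback earlier.

    Parameters
    ----------
    asymptote:
        Final temperature of the response.  Supply it when the trace is
        a short pulse that does not saturate (e.g. from a simulated
        saturation run); defaults to the last sample, which requires the
        trace to have effectively reached steady state.
    """
    t = trace.times - trace.step_time
    sel = t >= 0
    t = t[sel]
    temp = trace.temperatures[sel]
    if t.size < 10:
        raise IdentificationError("too few samples after the step")
    T0 = float(temp[0])
    T_end = float(asymptote) if asymptote is not None else float(temp[-1])
    dT_total = T_end - T0
    if dT_total <= 0:
        raise IdentificationError("no heating observed after the step")

    # noise tolerance: 3x robust SD of the detrended trace
    smooth = _moving_average(temp, 5)
    detrended = temp - smooth
    noise_sd = 1.4826 * float(np.median(np.abs(detrended - np.median(detrended))))
    if asymptote is None:
        # wide smoothing so the check responds to sustained cooling, not
        # to sample-to-sample noise excursions
        wide = _moving_average(temp, max(5, (temp.size // 50) | 1))
        dips = np.maximum.accumulate(wide) - wide
        if float(dips.max()) > max(3.0 * noise_sd, 1e-9 * abs(dT_total)):
            raise IdentificationError(
                "heating segment is non-monotone beyond noise tolerance"
            )
    dTdt = np.gradient(smooth, t)
    i_max = int(np.argmax(dTdt))
    tau1_infl = float(t[i_max])

    crossed = smooth - T0 >= 0.63 * dT_total
    if not crossed.any():
        if asymptote is None:
            raise IdentificationError(
                "trace never reaches 63% of the total gain"
            )
        # short pulse: the 63% crossing lies beyond the record; read it
        # off the fitted curve afterwards
        tau63 = None
        tau2_infl = max(float(t[-1]), 2 * trace.dt)
    else:
        i63 = int(np.argmax(crossed))
        if i63 == 0:
            tau63 = float(t[0])
        else:
            y0, y1 = smooth[i63 - 1] - T0, smooth[i63] - T0
            frac = (0.63 * dT_total - y0) / (y1 - y0)
            tau63 = float(t[i63 - 1] + frac * (t[i63] - t[i63 - 1]))
        tau2_infl = max(tau63 - tau1_infl, trace.dt)
    tau1_graph = max(min(tau1_infl, 0.99 * tau2_infl), 0.25 * trace.dt)
    g = static_gain(dT_total, trace.u_step)

    graph_resid = (
        _rms(temp - T0 - _step_shape(t, dT_total, tau1_graph, tau2_infl))
        if tau63 is not None else math.inf
    )

    # two-exponential least-squares fit, seeded by the graphical readings
    fit_plant = None
    fit_resid = math.inf
    try:
        popt, _ = curve_fit(
            _step_shape,
            t,
            temp - T0,
            p0=(dT_total, tau1_graph, tau2_infl),
            bounds=([0.0, 1e-6, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        dT_fit, tau_a, tau_b = popt
        tau1_fit, tau2_fit = sorted((tau_a, tau_b))
        if tau1_fit >= tau2_fit:  # degenerate repeated pole
            tau1_fit = 0.999 * tau2_fit
        fit_resid = _rms(temp - T0 - _step_shape(t, dT_fit, tau1_fit, tau2_fit))
        g_fit = static_gain(
            dT_fit if asymptote is None else dT_total, trace.u_step
        )
        fit_plant = PlantParams(g=g_fit, tau1=tau1_fit, tau2=tau2_fit)
    except (RuntimeError, ValueError) as exc:
        warnings.warn(f"two-exponential fit failed ({exc}); using graphical readings")

    if fit_plant is not None and fit_resid <= max(graph_resid, fit_tolerance_rms):
        if tau63 is None:
            # read the 63% time off the fitted saturation curve
            from scipy.optimize import brentq
            tau63 = float(brentq(
                lambda tv: _step_shape(
                    np.array([tv]), 1.0, fit_plant.tau1, fit_plant.tau2
                )[0] - 0.63,
                1e-9, 100.0 * fit_plant.tau2,
            ))
        return IdentificationResult(
            plant=fit_plant,
            method="two-exponential fit",
            residual_rms=fit_resid,
            tau1_inflection=tau1_infl,
            tau63=tau63,
        )
    if tau63 is None:
        raise IdentificationError(
            "short pulse: the saturation fit failed and no graphical "
            "reading is possible"
        )
    return IdentificationResult(
        plant=PlantParams(g=g, tau1=tau1_graph, tau2=tau2_infl),
        method="inflection",
        residual_rms=graph_resid,
        tau1_inflection=tau1_infl,
        tau63=tau63,
    )


def natural_frequency_from_period(period: float) -> float:
    """omega_n = 2 pi / period (rad/s)."""
    if period <= 0:
        raise ValueError("period must be positive")
    return 2.0 * math.pi / period


def estimate_period_from_oscillation(trace: TemperatureTrace) -> float:
    """Mean spacing of successive oscillation maxima, in seconds.

    The trace is pre-smoothed with a 5-sample moving average; peaks must
    rise above the noise floor (robust SD of the detrended signal).  At
    least three maxima are required.
    """
    temp = np.asarray(trace.T_probe_C, dtype=float)
    smooth = _moving_average(temp, 5)
    resid = temp - smooth
    noise = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    peaks, _ = find_peaks(smooth, prominence=max(3.0 * noise, 1e-12))
    if peaks.size < 3:
        raise IdentificationError("need at least 3 oscillation maxima")
    spacings = np.diff(trace.time_s[peaks])
    return float(np.mean(spacings))


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1 or x.size < n:
        return x.astype(float, copy=True)
    kernel = np.ones(n) / n
    pad = n // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad:-pad]
    return out


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))
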