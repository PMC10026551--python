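"""Uniformly sampled temperature/control traces and their CSV dialect.

A :class:`TemperatureTrace` is the common currency of the toolkit: the
plant simulators produce them, the identification and verification
routines consume them.  On disk a trace is a plain UTF-8 CSV with a
``time_s`` column plus any of the optional channels below; round-trips
are exact to well below 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: Column order of the on-disk dialect.  ``time_s`` and ``T_probe_C`` are
#: mandatory, the rest optional.
TRACE_COLUMNS = (
    "time_s",
    "T_probe_C",
    "T_safety_C",
    "u_V",
    "H_kA_per_m",
    "gated",
    "cem43_min",
)

_UNIFORMITY_RTOL = 1e-9


class TraceParseError(ValueError):
    """Raised when a trace file violates the CSV dialect."""


@dataclass
class TemperatureTrace:
    """Uniformly sampled record of a heating run.

    Parameters
    ----------
    time_s:
        Strictly increasing, uniformly spaced sample times in seconds.
    T_probe_C:
        Control-probe temperature in deg C.
    T_safety_C, u_V, H_kA_per_m, gated, cem43_min:
        Optional channels: safety-probe temperature, commanded actuator
        voltage, applied field amplitude, safety-gate flag (0/1) and the
        running CEM43 dose in minutes.
    """

    time_s: np.ndarray
    T_probe_C: np.ndarray
    T_safety_C: Optional[np.ndarray] = None
    u_V: Optional[np.ndarray] = None
    H_kA_per_m: Optional[np.ndarray] = None
    gated: Optional[np.ndarray] = None
    cem43_min: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.T_probe_C = np.asarray(self.T_probe_C, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.size < 2:
            raise TraceParseError("trace needs at least two samples")
        if self.T_probe_C.shape != self.time_s.shape:
            raise TraceParseError("T_probe_C length does not match time_s")
        steps = np.diff(self.time_s)
        if np.any(steps <= 0):
            row = int(np.argmax(steps <= 0)) + 1
            raise TraceParseError(
                f"time_s not strictly increasing at row {row}"
            )
        dt = steps[0]
        bad = np.abs(steps - dt) > _UNIFORMITY_RTOL * max(abs(dt), 1.0)
        if np.any(bad):
            row = int(np.argmax(bad)) + 1
            raise TraceParseError(f"non-uniform sampling at row {row}")
        for name in ("T_safety_C", "u_V", "H_kA_per_m", "gated", "cem43_min"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col, dtype=float)
                if col.shape != self.time_s.shape:
                    raise TraceParseError(f"{name} length mismatch")
                setattr(self, name, col)
        if self.gated is not None and not np.all(np.isin(self.gated, (0.0, 1.0))):
            raise TraceParseError("gated channel must be 0/1")

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return self.time_s.size

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(self.time_s[1] - self.time_s[0])

    @property
    def duration(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    # -- conversion ------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        data = {"time_s": self.time_s, "T_probe_C": self.T_probe_C}
        for name in TRACE_COLUMNS[2:]:
            col = getattr(self, name)
            if col is not None:
                data[name] = col
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TemperatureTrace":
        for required in ("time_s", "T_probe_C"):
            if required not in df.columns:
                raise TraceParseError(f"missing column {required!r}")
        unknown = set(df.columns) - set(TRACE_COLUMNS)
        if unknown:
            raise TraceParseError(f"unknown columns {sorted(unknown)}")
        kwargs = {c: df[c].to_numpy(dtype=float) for c in df.columns}
        return cls(**kwargs)


def write_trace(trace: TemperatureTrace, path: str | Path) -> None:
    """Write a trace to CSV (comma separator, '.' decimal, UTF-8)."""
    trace.to_dataframe().to_csv(path, index=False)


def read_trace(path: str | Path) -> TemperatureTrace:
    """Read a trace CSV, validating columns and time uniformity."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise TraceParseError(str(exc)) from exc
    return TemperatureTrace.from_dataframe(df)
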