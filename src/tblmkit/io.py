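"""CSV readers/writers for traces and conductance-temperature series.

File conventions: UTF-8, '.' decimal separator, mandatory header rows,
Celsius at the file boundary (kelvin internally), 17 significant digits on
write so write -> read round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .constants import CELSIUS_OFFSET
from .errors import ParseError, ValidationError
from .thermal import ConductanceSeries
from .trace import VITrace

__all__ = [
    "TRACE_COLUMNS",
    "SERIES_COLUMNS",
    "read_trace_csv",
    "write_trace_csv",
    "read_series_csv",
    "write_series_csv",
]

TRACE_COLUMNS = ("time_s", "voltage_V", "current_A")
SERIES_COLUMNS = ("temperature_C", "conductance_S")

_FLOAT_FMT = "%.17g"


def _read_numeric_csv(path: Union[str, Path], columns: tuple) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    try:
        df = pd.read_csv(path, encoding="utf-8",
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"{path}: {exc}") from exc
    if tuple(df.columns) != columns:
        raise ParseError(
            f"{path}: expected header {','.join(columns)!r}, "
            f"got {','.join(map(str, df.columns))!r}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | ~np.isfinite(numeric).all(axis=1)
    if bad.any():
        # +2: one for the header row, one for 1-based line numbering
        lines = [str(int(i) + 2) for i in numeric.index[bad][:10]]
        raise ParseError(
            f"{path}: non-numeric or non-finite cells on line(s) "
            + ", ".join(lines)
        )
    return numeric


def read_trace_csv(
    path: Union[str, Path], ramp_rate: float = None
) -> VITrace:
    """Read a V-I ramp trace (columns ``time_s, voltage_V, current_A``).

    ``ramp_rate`` (V/s) is inferred from the voltage/time columns when not
    declared explicitly.
    """
    df = _read_numeric_csv(path, TRACE_COLUMNS)
    t = df["time_s"].to_numpy()
    v = df["voltage_V"].to_numpy()
    i = df["current_A"].to_numpy()
    if ramp_rate is None:
        peak = int(np.argmax(v))
        if peak < 1 or t[peak] == t[0]:
            raise ParseError(
                f"{path}: cannot infer ramp_rate from a non-rising trace"
            )
        ramp_rate = float((v[peak] - v[0]) / (t[peak] - t[0]))
    try:
        return VITrace(time=t, voltage=v, current=i, ramp_rate=ramp_rate)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_trace_csv(trace: VITrace, path: Union[str, Path]) -> None:
    df = pd.DataFrame({
        "time_s": trace.time,
        "voltage_V": trace.voltage,
        "current_A": trace.current,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


def read_series_csv(
    path: Union[str, Path], sweep_direction: str = None
) -> ConductanceSeries:
    """Read a conductance series (columns ``temperature_C, conductance_S``).

    Temperatures convert from Celsius to kelvin on read; the sweep direction
    is inferred from the temperature ordering unless declared.
    """
    df = _read_numeric_csv(path, SERIES_COLUMNS)
    t = df["temperature_C"].to_numpy() + CELSIUS_OFFSET
    g = df["conductance_S"].to_numpy()
    if sweep_direction is None:
        sweep_direction = "warming" if len(t) < 2 or t[-1] >= t[0] \
            else "cooling"
    try:
        return ConductanceSeries(temperature=t, conductance=g,
                                 sweep_direction=sweep_direction)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_series_csv(series: ConductanceSeries, path: Union[str, Path]) -> None:
    df = pd.DataFrame({
        "temperature_C": series.temperature - CELSIUS_OFFSET,
        "conductance_S": series.conductance,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")
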