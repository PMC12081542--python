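"""Arrhenius analysis of membrane conductance-temperature series.

Membrane conduction is thermally activated: G(T) = A exp(-Ea / R T), so
ln G is linear in 1/T with slope -Ea/R.  The fit is ordinary least squares
of ln G on 1/T; the slope is also reported on the conventional 10^3/T plot
axis.  A sequential changepoint detector flags the irreversible conductance
jump that marks xenon desorbing from the bilayer on warming (observed near
24 degC); fits can then be restricted to the event-free prefix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .constants import CELSIUS_OFFSET, R_GAS
from .errors import DomainError, InsufficientDataError, ValidationError

__all__ = [
    "ConductanceSeries",
    "ArrheniusFit",
    "DiscontinuityEvent",
    "arrhenius_fit",
    "detect_discontinuity",
    "fit_with_truncation",
]


@dataclass
class ConductanceSeries:
    """Membrane conductance sampled along a monotone temperature sweep.

    Temperatures are kelvin internally; Celsius only at file boundaries.
    """

    temperature: np.ndarray
    conductance: np.ndarray
    sweep_direction: str = "warming"

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.conductance = np.asarray(self.conductance, dtype=float)
        if len(self.temperature) != len(self.conductance):
            raise ValidationError(
                "temperature/conductance: arrays must have equal length"
            )
        if len(self.temperature) < 3:
            raise ValidationError("temperature: need at least 3 points")
        if np.any(self.conductance <= 0):
            raise ValidationError("conductance: all values must be > 0")
        if self.sweep_direction not in ("warming", "cooling"):
            raise ValidationError(
                "sweep_direction: must be 'warming' or 'cooling'"
            )
        d = np.diff(self.temperature)
        if self.sweep_direction == "warming" and not np.all(d > 0):
            raise ValidationError(
                "temperature: must be strictly increasing in a warming sweep"
            )
        if self.sweep_direction == "cooling" and not np.all(d < 0):
            raise ValidationError(
                "temperature: must be strictly decreasing in a cooling sweep"
            )

    def __len__(self) -> int:
        return len(self.temperature)

    def prefix(self, n: int) -> "ConductanceSeries":
        return ConductanceSeries(self.temperature[:n], self.conductance[:n],
                                 self.sweep_direction)


@dataclass(frozen=True)
class ArrheniusFit:
    """OLS fit of ln G on 1/T and the derived activation energy."""

    slope: float            # kelvin (negative for Ea > 0)
    intercept: float        # ln siemens
    activation_energy: float  # J/mol, = -slope * R
    r_squared: float
    n_points: int

    @property
    def slope_per_kilokelvin(self) -> float:
        """Slope on the 10^3/T plot axis (the conventional Arrhenius plot)."""
        return self.slope / 1000.0

    def predict(self, temperature: np.ndarray) -> np.ndarray:
        """Model conductance at the given kelvin temperatures."""
        t = np.asarray(temperature, dtype=float)
        return np.exp(self.intercept + self.slope / t)


@dataclass(frozen=True)
class DiscontinuityEvent:
    """First point inconsistent with the Arrhenius trend of its predecessors."""

    index: int
    temperature: float      # kelvin
    ratio: float            # observed / Arrhenius-predicted conductance
    z_score: float

    @property
    def temperature_celsius(self) -> float:
        return self.temperature - CELSIUS_OFFSET


def _ols(x: np.ndarray, y: np.ndarray):
    """Slope, intercept, SSE, r^2 of y on x; r^2 = 1 for a zero-variance y."""
    n = len(x)
    xm, ym = np.mean(x), np.mean(y)
    sxx = float(np.dot(x - xm, x - xm))
    syy = float(np.dot(y - ym, y - ym))
    sxy = float(np.dot(x - xm, y - ym))
    slope = sxy / sxx if sxx > 0 else 0.0
    intercept = ym - slope * xm
    sse = max(syy - (sxy * sxy / sxx if sxx > 0 else 0.0), 0.0)
    r2 = 1.0 - sse / syy if syy > 0 else 1.0
    return slope, intercept, sse, min(max(r2, 0.0), 1.0), n


def arrhenius_fit(series: ConductanceSeries) -> ArrheniusFit:
    """Activation energy from the slope of ln G versus 1/T.

    Ea = -slope * R with R = 8.314 J/(mol K).  A constant-conductance series
    gives slope 0 and Ea 0.

    >>> s = ConductanceSeries([283.15, 289.15, 295.15], [1e-7, 1e-7, 1e-7])
    >>> arrhenius_fit(s).activation_energy
    0.0
    """
    if len(series) < 3:
        raise InsufficientDataError("Arrhenius fit needs at least 3 points")
    if np.any(series.conductance <= 0):
        raise DomainError("conductance: must be > 0 to take logarithms")
    x = 1.0 / series.temperature
    y = np.log(series.conductance)
    slope, intercept, _sse, r2, n = _ols(x, y)
    return ArrheniusFit(slope=slope, intercept=intercept,
                        activation_energy=-slope * R_GAS,
                        r_squared=r2, n_points=n)


def _robust_log_scale(y: np.ndarray) -> float:
    """Robust SD of the ln G noise from successive differences.

    The Arrhenius trend contributes a nearly constant increment per step,
    which the median removes; the MAD of the de-medianed differences, scaled
    by 1.4826 and 1/sqrt(2), estimates the per-point ln-noise SD even when a
    single desorption jump contaminates the series.
    """
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / np.sqrt(2.0)


def detect_discontinuity(
    series: ConductanceSeries,
    z_threshold: float = 5.0,
    min_seed_points: int = 2,
    force: bool = False,
) -> Optional[DiscontinuityEvent]:
    """Sequentially flag the first point off its predecessors' Arrhenius trend.

    For each index i (from ``min_seed_points`` on), the points before i are
    fitted and the standardized one-step-ahead ln-residual of point i
    computed; the first |z| above ``z_threshold`` is returned as the event.
    The standardization scale is the larger of the running fit's residual SD
    and a robust noise-SD estimate from successive ln G differences (with a
    1e-12 floor), inflated by the OLS prediction-leverage factor
    sqrt(1 + 1/n + (x_i - x_bar)^2 / S_xx) — without the leverage term the
    extrapolation error of a 2-3 point seed fit masquerades as a jump and
    the false-alarm rate at the earliest indices is far above nominal.

    Desorption only occurs on warming; cooling sweeps return None unless
    ``force`` is set.
    """
    if len(series) < 4:
        raise InsufficientDataError(
            "discontinuity detection needs at least 4 points"
        )
    if series.sweep_direction != "warming" and not force:
        return None
    x = 1.0 / series.temperature
    y = np.log(series.conductance)
    robust = _robust_log_scale(y)
    for i in range(max(min_seed_points, 2), len(series)):
        slope, intercept, sse, _r2, n = _ols(x[:i], y[:i])
        sd_fit = np.sqrt(sse / (n - 2)) if n > 2 else 0.0
        xm = np.mean(x[:i])
        sxx = float(np.dot(x[:i] - xm, x[:i] - xm))
        leverage = 1.0 + 1.0 / n + ((x[i] - xm) ** 2 / sxx if sxx > 0 else 0.0)
        scale = max(sd_fit, robust, 1e-12) * np.sqrt(leverage)
        resid = y[i] - (intercept + slope * x[i])
        z = abs(resid) / scale
        if z > z_threshold:
            return DiscontinuityEvent(
                index=i,
                temperature=float(series.temperature[i]),
                ratio=float(np.exp(resid)),
                z_score=float(z),
            )
    return None


def fit_with_truncation(
    series: ConductanceSeries,
    z_threshold: float = 5.0,
) -> Tuple[ArrheniusFit, Optional[DiscontinuityEvent]]:
    """Arrhenius fit on the longest discontinuity-free prefix.

    Conductance-temperature sweeps through a desorption event mix two
    membrane states; truncating at the event keeps the fit to the
    xenon-containing state.  Event-free series give the plain fit.
    """
    event = (detect_discontinuity(series, z_threshold=z_threshold)
             if len(series) >= 4 else None)
    if event is None:
        return arrhenius_fit(series), None
    if event.index < 3:
        raise InsufficientDataError(
            f"event at index {event.index} leaves fewer than 3 points to fit"
        )
    return arrhenius_fit(series.prefix(event.index)), event
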