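"""Equivalent-circuit simulator for tethered-bilayer electrical measurements.

Stands in for the instrument: emits stepped-ramp V-I traces (capacitive
charging pedestal plus a three-region piecewise-linear conductive current)
and Arrhenius-distributed conductance-temperature sweeps, including the
irreversible conductance jump seen near 24 degC when dissolved xenon leaves
the bilayer on warming.

Scenario presets encode the qualitative physics: xenon lowers membrane
capacitance and high-voltage conductance, raises the conduction activation
energy, and has a larger effect the sparser the tethering (T1 > T10 > T100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .constants import CELSIUS_OFFSET, R_GAS, ROOM_TEMPERATURE
from .errors import PresetLookupError, ValidationError
from .thermal import ConductanceSeries
from .trace import VITrace

__all__ = [
    "RampProtocol",
    "MembraneScenario",
    "ThermalScenario",
    "simulate_vi_trace",
    "simulate_gt_series",
    "conductive_current",
    "scenario_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class RampProtocol:
    """Stepped triangular voltage ramp.

    Defaults follow the chip-reader protocol: 0 to 500 mV in 5 mV increments
    every 0.05 ms (ramp rate 100 V/s), current averaged over a 0.01 ms window
    after each increment.
    """

    v_start: float = 0.0
    v_max: float = 0.5
    step_height: float = 5e-3
    step_duration: float = 5e-5
    averaging_window: float = 1e-5

    def __post_init__(self) -> None:
        if self.v_start < 0:
            raise ValidationError("v_start: must be >= 0")
        if not self.v_max > self.v_start:
            raise ValidationError("v_max: must exceed v_start")
        if not self.step_height > 0:
            raise ValidationError("step_height: must be > 0")
        if not self.step_duration > 0:
            raise ValidationError("step_duration: must be > 0")
        if not 0 < self.averaging_window <= self.step_duration:
            raise ValidationError(
                "averaging_window: must be in (0, step_duration]"
            )
        if not np.isfinite(self.ramp_rate):
            raise ValidationError("step_height/step_duration: ramp rate "
                                  "must be finite")

    @property
    def ramp_rate(self) -> float:
        """dV/dt in V/s."""
        return self.step_height / self.step_duration

    @property
    def n_steps(self) -> int:
        return int(round((self.v_max - self.v_start) / self.step_height))

    def step_voltages(self) -> np.ndarray:
        """Voltage after each increment (one sample per step)."""
        return self.v_start + self.step_height * np.arange(1, self.n_steps + 1)


@dataclass(frozen=True)
class MembraneScenario:
    """Ground-truth electrical parameters of a simulated membrane."""

    capacitance: float
    g_low: float
    g_high: float
    v_break1: float
    v_break2: float
    tether_density_label: str = "T10"
    xenon_saturation: float = 0.0
    noise_sd: float = 0.0
    series_resistance: float = 0.0

    def __post_init__(self) -> None:
        # 0 is allowed for a purely ohmic (capacitance-free) test scenario
        if self.capacitance < 0:
            raise ValidationError("capacitance: must be >= 0")
        for name in ("g_low", "g_high"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: must be >= 0")
        if not 0 <= self.v_break1 <= self.v_break2:
            raise ValidationError(
                "v_break1/v_break2: require 0 <= v_break1 <= v_break2"
            )
        if self.tether_density_label not in ("T1", "T10", "T100"):
            raise ValidationError(
                "tether_density_label: must be one of T1, T10, T100"
            )
        if not 0 <= self.xenon_saturation <= 1:
            raise ValidationError("xenon_saturation: must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be >= 0")
        if self.series_resistance < 0:
            raise ValidationError("series_resistance: must be >= 0")


@dataclass(frozen=True)
class ThermalScenario:
    """Arrhenius-conducting membrane for conductance-temperature sweeps.

    ``g_ref`` anchors the conductance at ``ref_temperature``; if
    ``desorption_temp`` is set and a warming sweep crosses it, every
    subsequent point jumps irreversibly to ``baseline_after_desorption``
    (xenon lost from the bilayer).
    """

    g_ref: float
    activation_energy: float
    temp_range: tuple
    noise_cv: float = 0.0
    ref_temperature: float = ROOM_TEMPERATURE
    desorption_temp: Optional[float] = None
    baseline_after_desorption: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "temp_range", tuple(self.temp_range))
        if len(self.temp_range) == 0:
            raise ValidationError("temp_range: must not be empty")
        t = np.asarray(self.temp_range, dtype=float)
        if len(t) > 1:
            d = np.diff(t)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValidationError(
                    "temp_range: temperatures must be strictly monotone"
                )
        if not self.g_ref > 0:
            raise ValidationError("g_ref: must be > 0")
        if self.activation_energy < 0:
            raise ValidationError("activation_energy: must be >= 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv: must be >= 0")
        if not self.ref_temperature > 0:
            raise ValidationError("ref_temperature: must be > 0 kelvin")
        if self.desorption_temp is not None:
            if self.baseline_after_desorption is None or \
                    not self.baseline_after_desorption > 0:
                raise ValidationError(
                    "baseline_after_desorption: must be > 0 when "
                    "desorption_temp is set"
                )

    @property
    def sweep_direction(self) -> str:
        t = np.asarray(self.temp_range, dtype=float)
        if len(t) < 2 or t[-1] >= t[0]:
            return "warming"
        return "cooling"


def conductive_current(
    voltage: Union[float, np.ndarray], scenario: MembraneScenario
) -> np.ndarray:
    """Noiseless conductive current I_cond(V).

    Piecewise: slope ``g_low`` through the origin for V <= v_break1, slope
    ``g_high`` for V >= v_break2, and the C1 Hermite cubic between them whose
    endpoint value at v_break2 is set by the mean slope (g_low + g_high)/2 —
    the choice that keeps the cubic monotone for any non-negative pair of
    conductances.
    """
    v = np.asarray(voltage, dtype=float)
    v1, v2 = scenario.v_break1, scenario.v_break2
    gl, gh = scenario.g_low, scenario.g_high
    if gl == gh:  # single line; keep the ohmic case exact in floats
        out = gl * v
        return out if out.ndim else float(out)
    y1 = gl * v1
    if v2 > v1:
        y2 = y1 + 0.5 * (gl + gh) * (v2 - v1)
        h = v2 - v1
        with np.errstate(over="ignore"):
            t = np.clip((v - v1) / h, 0.0, 1.0)
        h00 = (1 + 2 * t) * (1 - t) ** 2
        h10 = t * (1 - t) ** 2
        h01 = t * t * (3 - 2 * t)
        h11 = t * t * (t - 1)
        cubic = h00 * y1 + h10 * h * gl + h01 * y2 + h11 * h * gh
    else:
        y2 = y1
        cubic = np.full_like(v, y1)
    out = np.where(
        v <= v1, gl * v,
        np.where(v >= v2, y2 + gh * (v - v2), cubic),
    )
    return out if out.ndim else float(out)


def simulate_vi_trace(
    protocol: RampProtocol,
    scenario: MembraneScenario,
    seed: Optional[int] = None,
    include_falling: bool = False,
) -> VITrace:
    """One current sample per voltage step of the ramp.

    Noiseless current at step voltage V is ``C * dV/dt + I_cond(V)`` on the
    rising limb (``-C * dV/dt + I_cond(V)`` on the optional falling limb);
    additive zero-mean Gaussian noise of SD ``noise_sd`` is applied per
    sample.  A fixed seed makes the trace bit-identical across runs.
    """
    v_up = protocol.step_voltages()
    i_cap = scenario.capacitance * protocol.ramp_rate
    i_up = i_cap + conductive_current(v_up, scenario)
    if include_falling:
        v_down = v_up[::-1][1:] - protocol.step_height
        i_down = -i_cap + conductive_current(v_down, scenario)
        voltage = np.concatenate([v_up, v_down])
        current = np.concatenate([i_up, i_down])
    else:
        voltage, current = v_up, i_up
    if scenario.series_resistance > 0:
        # ideal-electrode default; small ohmic drop model when enabled
        current = current / (1.0 + scenario.series_resistance *
                             (scenario.g_low + scenario.g_high) / 2.0)
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, scenario.noise_sd, len(current))
    time = protocol.step_duration * np.arange(1, len(voltage) + 1)
    return VITrace(time=time, voltage=voltage, current=current,
                   ramp_rate=protocol.ramp_rate)


def simulate_gt_series(
    scenario: ThermalScenario, seed: Optional[int] = None
) -> ConductanceSeries:
    """Arrhenius conductance-temperature sweep with lognormal noise.

    Noiseless conductance follows
    ``G(T) = g_ref * exp(-Ea/R * (1/T - 1/T_ref))``.  Multiplicative noise is
    lognormal with unit median and ln-SD ``sqrt(ln(1 + cv^2))`` so the
    ln G residuals the Arrhenius fit sees are zero-mean Gaussian.  In a
    warming sweep that crosses ``desorption_temp``, all points at or beyond
    the crossing are replaced by ``baseline_after_desorption`` (irreversible
    xenon loss).
    """
    t = np.asarray(scenario.temp_range, dtype=float)
    if len(t) == 0:
        raise ValidationError("temp_range: must not be empty")
    g = scenario.g_ref * np.exp(
        -scenario.activation_energy / R_GAS * (1.0 / t -
                                               1.0 / scenario.ref_temperature)
    )
    if (scenario.desorption_temp is not None
            and scenario.sweep_direction == "warming"):
        crossed = t >= scenario.desorption_temp
        if crossed.any() and not crossed.all():
            g = np.where(crossed, scenario.baseline_after_desorption, g)
    if scenario.noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(scenario.noise_cv ** 2))
        g = g * np.exp(rng.normal(0.0, sigma, len(t)))
    return ConductanceSeries(temperature=t, conductance=g,
                             sweep_direction=scenario.sweep_direction)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _vi(c_nf, g_low_us, g_high_us, label, xe):
    # noise default: 1% of the full-scale current (capacitive pedestal at
    # 100 V/s plus the high-region conductive current at 500 mV)
    full_scale = c_nf * 1e-9 * 100.0 + g_high_us * 1e-6 * 0.5
    return MembraneScenario(
        capacitance=c_nf * 1e-9,
        g_low=g_low_us * 1e-6,
        g_high=g_high_us * 1e-6,
        v_break1=0.15,
        v_break2=0.30,
        tether_density_label=label,
        xenon_saturation=xe,
        noise_sd=0.01 * full_scale,
    )


_THERMAL_T = tuple(283.15 + 1.0 * k for k in range(13))  # 10..22 degC warming

PRESETS = {
    # V-I scenarios; capacitance and onset follow the measured 24 -> 20 nF
    # drop with xenon, conductances are illustrative but preserve the
    # observed orderings (xenon lowers g_high; effect size T1 > T10 > T100).
    "lipid_only": _vi(24, 0.9, 8.0, "T10", 0.0),
    "xe10": _vi(20, 0.9, 4.0, "T10", 0.10),
    "xe30": _vi(20, 0.85, 3.8, "T10", 0.30),
    "lipid_only_T1": _vi(24, 1.2, 10.0, "T1", 0.0),
    "xe10_T1": _vi(20, 1.1, 3.0, "T1", 0.10),
    "lipid_only_T10": _vi(24, 0.9, 8.0, "T10", 0.0),
    "xe10_T10": _vi(20, 0.9, 4.0, "T10", 0.10),
    "lipid_only_T100": _vi(24, 0.6, 6.0, "T100", 0.0),
    "xe10_T100": _vi(20, 0.55, 5.0, "T100", 0.10),
    # thermal scenarios; Ea values are the reported activation energies
    "thermal_lipid": ThermalScenario(
        g_ref=9e-7, activation_energy=73e3, temp_range=_THERMAL_T,
        noise_cv=0.02,
    ),
    "thermal_xe10": ThermalScenario(
        g_ref=9e-7, activation_energy=84e3, temp_range=_THERMAL_T,
        noise_cv=0.02,
    ),
    # warming past 24 degC: irreversible desorption jump
    "thermal_xe10_desorption": ThermalScenario(
        g_ref=9e-7, activation_energy=84e3,
        temp_range=tuple(283.15 + 1.0 * k for k in range(17)),  # 10..26 degC
        noise_cv=0.02,
        desorption_temp=24.0 + CELSIUS_OFFSET,
        baseline_after_desorption=5e-6,
    ),
}


def scenario_preset(name: str):
    """Look up a documented scenario preset by name.

    Returns a fully populated :class:`MembraneScenario` or
    :class:`ThermalScenario`; unknown names raise listing the valid ones.
    """
    try:
        return PRESETS[name]
    except KeyError:
        raise PresetLookupError(
            f"unknown preset {name!r}; valid presets: "
            + ", ".join(sorted(PRESETS))
        ) from None
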