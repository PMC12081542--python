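"""End-to-end pipeline: simulate -> segment -> Arrhenius -> pore properties.

Configuration is a plain-text INI file with ``[membrane] [protocol]
[analysis] [simulate] [output]`` sections; unknown keys are rejected.  Given
a seed the pipeline is deterministic: JSON reports are byte-identical across
runs, and a provenance log echoes every physical constant used, each exactly
once.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import constants as C
from .errors import ConfigError, PipelineStageError, TblmError
from .pores import MembraneSpec, full_chain
from .synthetic import (
    RampProtocol,
    scenario_preset,
    simulate_gt_series,
    simulate_vi_trace,
)
from .thermal import fit_with_truncation
from .trace import segment_vi, to_specific
from .io import write_series_csv, write_trace_csv

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "render_report"]

logger = logging.getLogger("tblmkit")

_SECTION_KEYS = {
    "membrane": {"area", "thickness", "electrolyte_conductivity",
                 "temperature", "eps_water", "eps_membrane", "ion_charge"},
    "protocol": {"v_start", "v_max", "step_height", "step_duration",
                 "averaging_window"},
    "analysis": {"onset_steps", "z_threshold", "aqueous_term_J_mol",
                 "radius_m", "barrier_model", "warn_specific_c"},
    "simulate": {"scenario", "thermal_scenario", "seed"},
    "output": {"directory"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    protocol: RampProtocol = field(default_factory=RampProtocol)
    onset_steps: int = 1
    z_threshold: float = 5.0
    aqueous_term_J_mol: float = C.AQUEOUS_ELECTRODIFFUSION_EA
    radius_m: Optional[float] = 3e-11
    barrier_model: str = "image-charge"
    warn_specific_c: float = C.BARE_ELECTRODE_WARN_SPECIFIC_C
    scenario: str = "xe10"
    thermal_scenario: str = "thermal_xe10"
    seed: int = 0
    output_dir: Path = Path("tblm_out")

    def __post_init__(self) -> None:
        if not 1 <= self.onset_steps <= 5:
            raise ConfigError("analysis.onset_steps: must be in [1, 5]")
        if self.z_threshold <= 0:
            raise ConfigError("analysis.z_threshold: must be > 0")
        self.output_dir = Path(self.output_dir)


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Parse and validate an INI config file; unknown keys are errors."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"{path}: config file does not exist")
    parser = configparser.ConfigParser()
    parser.optionxform = str  # keys are case-sensitive (units in names)
    try:
        parser.read(path, encoding="utf-8")
    except configparser.Error as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    for section in parser.sections():
        if section not in _SECTION_KEYS:
            raise ConfigError(f"{path}: unknown section [{section}]")
        unknown = set(parser[section]) - _SECTION_KEYS[section]
        if unknown:
            raise ConfigError(
                f"{path}: unknown key(s) in [{section}]: "
                + ", ".join(sorted(unknown))
            )

    def fval(section, key, default):
        if parser.has_option(section, key):
            return parser.getfloat(section, key)
        return default

    try:
        membrane = MembraneSpec(
            area=fval("membrane", "area", C.ELECTRODE_AREA),
            thickness=fval("membrane", "thickness", C.BILAYER_THICKNESS),
            electrolyte_conductivity=fval(
                "membrane", "electrolyte_conductivity", C.SIGMA_PBS),
            temperature=fval("membrane", "temperature", C.ROOM_TEMPERATURE),
            eps_water=fval("membrane", "eps_water", C.EPS_WATER),
            eps_membrane=fval("membrane", "eps_membrane", C.EPS_MEMBRANE),
            ion_charge=fval("membrane", "ion_charge", C.ELEMENTARY_CHARGE),
        )
        protocol = RampProtocol(
            v_start=fval("protocol", "v_start", 0.0),
            v_max=fval("protocol", "v_max", 0.5),
            step_height=fval("protocol", "step_height", 5e-3),
            step_duration=fval("protocol", "step_duration", 5e-5),
            averaging_window=fval("protocol", "averaging_window", 1e-5),
        )
        radius = fval("analysis", "radius_m", 3e-11)
        return PipelineConfig(
            membrane=membrane,
            protocol=protocol,
            onset_steps=int(fval("analysis", "onset_steps", 1)),
            z_threshold=fval("analysis", "z_threshold", 5.0),
            aqueous_term_J_mol=fval("analysis", "aqueous_term_J_mol",
                                    C.AQUEOUS_ELECTRODIFFUSION_EA),
            radius_m=radius if radius > 0 else None,
            barrier_model=parser.get("analysis", "barrier_model",
                                     fallback="image-charge"),
            warn_specific_c=fval("analysis", "warn_specific_c",
                                 C.BARE_ELECTRODE_WARN_SPECIFIC_C),
            scenario=parser.get("simulate", "scenario", fallback="xe10"),
            thermal_scenario=parser.get("simulate", "thermal_scenario",
                                        fallback="thermal_xe10"),
            seed=int(fval("simulate", "seed", 0)),
            output_dir=parser.get("output", "directory",
                                  fallback="tblm_out"),
        )
    except ConfigError:
        raise
    except (TblmError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n",
                    encoding="utf-8")


def _digest(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(repr(a).encode())
    return h.hexdigest()[:12]


def _provenance_lines(cfg: PipelineConfig) -> list:
    """Every numeric constant used anywhere, echoed exactly once."""
    m = cfg.membrane
    return [
        f"R_gas_J_per_molK = {C.R_GAS}",
        f"k_boltzmann_J_per_K = {C.K_BOLTZMANN}",
        f"n_avogadro_per_mol = {C.N_AVOGADRO}",
        f"elementary_charge_C = {m.ion_charge}",
        f"eps0_F_per_m = {C.EPS0}",
        f"celsius_offset_K = {C.CELSIUS_OFFSET}",
        f"eps_water = {m.eps_water}",
        f"eps_membrane = {m.eps_membrane}",
        f"electrolyte_conductivity_S_per_m = {m.electrolyte_conductivity}",
        f"electrode_area_m2 = {m.area}",
        f"bilayer_thickness_m = {m.thickness}",
        f"temperature_K = {m.temperature}",
        f"aqueous_term_J_per_mol = {cfg.aqueous_term_J_mol}",
        f"bare_electrode_warn_specific_C_F_per_m2 = {cfg.warn_specific_c}",
        f"onset_steps = {cfg.onset_steps}",
        f"z_threshold = {cfg.z_threshold}",
        f"barrier_model = {cfg.barrier_model}",
        f"pore_radius_input_m = {cfg.radius_m}",
        f"seed = {cfg.seed}",
    ]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run simulate -> analyze-vi -> arrhenius -> pore-props -> report.

    Writes ``trace.csv``, ``gt_series.csv``, ``segmentation.json``,
    ``arrhenius.json``, ``pore_props.json``, ``report.txt`` and
    ``pipeline.log`` into the configured output directory and returns the
    assembled records as a dict.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "simulate-vi"
        scenario = scenario_preset(cfg.scenario)
        trace = simulate_vi_trace(cfg.protocol, scenario, seed=cfg.seed)
        write_trace_csv(trace, out / "trace.csv")

        stage = "analyze-vi"
        seg = segment_vi(trace)
        c_spec = to_specific(seg.capacitance, cfg.membrane.area, unit="F")
        if c_spec.specific > cfg.warn_specific_c:
            logger.warning(
                "specific capacitance %.3g F/m2 exceeds the bare-electrode "
                "threshold %.3g F/m2: no bilayer may be present",
                c_spec.specific, cfg.warn_specific_c,
            )
        segmentation = {
            "capacitance_F": seg.capacitance,
            "capacitance_specific_F_per_m2": c_spec.specific,
            "v_break1_V": seg.breakpoints[0],
            "v_break2_V": seg.breakpoints[1],
            "g_low_S": seg.g_low,
            "g_high_S": seg.g_high,
            "g_low_specific_S_per_m2": seg.g_low / cfg.membrane.area,
            "g_high_specific_S_per_m2": seg.g_high / cfg.membrane.area,
            "fit_sse_A2": seg.fit_sse,
        }
        _dump_json(segmentation, out / "segmentation.json")

        stage = "simulate-gt"
        thermal = scenario_preset(cfg.thermal_scenario)
        series = simulate_gt_series(thermal, seed=cfg.seed + 1)
        write_series_csv(series, out / "gt_series.csv")

        stage = "arrhenius"
        fit, event = fit_with_truncation(series, z_threshold=cfg.z_threshold)
        arrhenius = {
            "slope_K": fit.slope,
            "slope_per_kiloK": fit.slope_per_kilokelvin,
            "intercept_lnS": fit.intercept,
            "Ea_J_per_mol": fit.activation_energy,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
            "event": None if event is None else {
                "index": event.index,
                "temperature_C": event.temperature_celsius,
                "ratio": event.ratio,
            },
        }
        _dump_json(arrhenius, out / "arrhenius.json")

        stage = "pore-props"
        props = full_chain(
            activation_energy=fit.activation_energy,
            g_membrane_specific=seg.g_low / cfg.membrane.area,
            spec=cfg.membrane,
            radius=cfg.radius_m,
            model=cfg.barrier_model,
            aqueous_term=cfg.aqueous_term_J_mol,
        )
        pore_props = {
            "activation_energy_J_mol": props.activation_energy,
            "born_energy_J_mol": props.born_energy,
            "partition_coefficient": props.partition_coefficient,
            "pore_radius_m": props.pore_radius,
            "per_pore_conductance_S": props.per_pore_conductance,
            "specific_pore_conductivity_S_m2":
                props.specific_pore_conductivity,
            "pore_density_per_m2": props.pore_density,
        }
        _dump_json(pore_props, out / "pore_props.json")

        stage = "report"
        report = render_report([(cfg.scenario, pore_props)])
        (out / "report.txt").write_text(report, encoding="utf-8")
        log_lines = _provenance_lines(cfg)
        (out / "pipeline.log").write_text("\n".join(log_lines) + "\n",
                                          encoding="utf-8")
    except TblmError as exc:
        raise PipelineStageError(
            f"stage {stage!r} failed "
            f"(input digest {_digest(cfg.scenario, cfg.seed)}): {exc}"
        ) from exc

    return {"segmentation": segmentation, "arrhenius": arrhenius,
            "pore_props": pore_props, "report": report}


def render_report(records) -> str:
    """Render (label, pore_props dict) pairs as a fixed-width table."""
    header = (
        f"{'membrane':<24}{'Ea (J/mol)':>14}{'Gp (S/m2)':>14}"
        f"{'N (pores/m2)':>16}{'radius (m)':>14}"
    )
    lines = [header, "-" * len(header)]
    for label, rec in records:
        lines.append(
            f"{label:<24}"
            f"{rec['activation_energy_J_mol']:>14.3g}"
            f"{rec['specific_pore_conductivity_S_m2']:>14.3g}"
            f"{rec['pore_density_per_m2']:>16.3g}"
            f"{rec['pore_radius_m']:>14.3g}"
        )
    return "\n".join(lines) + "\n"
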