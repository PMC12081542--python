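"""Born-energy / pore-property chain for membrane conduction.

From the Arrhenius activation energy of membrane conduction the chain
derives, in order: the Born (electrostatic self-energy) barrier for moving
an ion into the low-dielectric membrane interior, W_B = Ea minus the aqueous
electrodiffusion term; the ion partition coefficient into a pore,
gamma = exp(-W_B / R T); the conductance of a single water-filled
cylindrical pore, g = gamma sigma pi r^2 / d; and the areal pore density
N = G_m / g that accounts for the measured specific membrane conductance.

Pore radius may be supplied directly or inverted from W_B through a
pluggable dielectric barrier model (a documented image-charge-style
approximation by default).  The interfacial free energy of the bilayer
surface, gamma_m = (mu_1,0 - mu_m,0 + kT ln X1) / a, links the lipid
monomer/bilayer equilibrium to pore formation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Union

import numpy as np
from scipy.optimize import brentq

from .constants import (
    AQUEOUS_ELECTRODIFFUSION_EA,
    BILAYER_THICKNESS,
    ELECTRODE_AREA,
    ELEMENTARY_CHARGE,
    EPS0,
    EPS_MEMBRANE,
    EPS_WATER,
    K_BOLTZMANN,
    N_AVOGADRO,
    R_GAS,
    ROOM_TEMPERATURE,
    SIGMA_PBS,
)
from .errors import DomainError, PresetLookupError, RangeError, ValidationError

__all__ = [
    "MembraneSpec",
    "PoreProperties",
    "LipidEquilibrium",
    "BarrierModel",
    "ImageChargeBarrier",
    "register_barrier_model",
    "get_barrier_model",
    "born_energy",
    "partition_coefficient",
    "per_pore_conductance",
    "pore_density",
    "pore_barrier",
    "invert_pore_radius",
    "interfacial_free_energy",
    "full_chain",
]


@dataclass(frozen=True)
class MembraneSpec:
    """Geometry, electrolyte and dielectric constants of the measured cell."""

    area: float = ELECTRODE_AREA
    thickness: float = BILAYER_THICKNESS
    electrolyte_conductivity: float = SIGMA_PBS
    temperature: float = ROOM_TEMPERATURE
    eps_water: float = EPS_WATER
    eps_membrane: float = EPS_MEMBRANE
    ion_charge: float = ELEMENTARY_CHARGE

    def __post_init__(self) -> None:
        for name in ("area", "thickness", "electrolyte_conductivity",
                     "temperature", "eps_water", "eps_membrane", "ion_charge"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name}: must be > 0")
        if not self.eps_water > self.eps_membrane >= 1:
            raise ValidationError(
                "eps_water/eps_membrane: require eps_water > eps_membrane >= 1"
            )


@dataclass(frozen=True)
class PoreProperties:
    """The assembled pore-property record (one membrane condition)."""

    born_energy: float                  # J/mol
    partition_coefficient: float        # dimensionless
    pore_radius: float                  # m
    per_pore_conductance: float         # S
    specific_pore_conductivity: float   # S/m^2 (per-pore / electrode area)
    pore_density: float                 # pores/m^2
    membrane_conductance_specific: float  # S/m^2
    activation_energy: float = float("nan")  # J/mol

    def __post_init__(self) -> None:
        if self.born_energy < 0:
            raise ValidationError("born_energy: must be >= 0")
        if not 0 < self.partition_coefficient <= 1:
            raise ValidationError("partition_coefficient: must be in (0, 1]")
        for name in ("pore_radius", "per_pore_conductance",
                     "specific_pore_conductivity", "pore_density",
                     "membrane_conductance_specific"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: must be >= 0")
        g_total = self.pore_density * self.per_pore_conductance
        ref = self.membrane_conductance_specific
        if ref > 0 and abs(g_total - ref) > 1e-12 * ref:
            raise ValidationError(
                "pore_density: pore_density * per_pore_conductance must "
                "reproduce membrane_conductance_specific"
            )


@dataclass(frozen=True)
class LipidEquilibrium:
    """Chemical equilibrium between bilayer lipids and dissolved monomers."""

    mu_monomer_std: float       # J
    mu_bilayer_std: float       # J
    mole_fraction_monomer: float
    area_per_molecule: float    # m^2
    temperature: float = ROOM_TEMPERATURE

    def __post_init__(self) -> None:
        if not self.area_per_molecule > 0:
            raise ValidationError("area_per_molecule: must be > 0")
        if not 0 < self.mole_fraction_monomer <= 1:
            raise ValidationError(
                "mole_fraction_monomer: must be in (0, 1]"
            )
        if not self.temperature > 0:
            raise ValidationError("temperature: must be > 0 kelvin")


def born_energy(
    activation_energy: float,
    aqueous_term: float = AQUEOUS_ELECTRODIFFUSION_EA,
) -> float:
    """Membrane Born barrier: total Ea minus the aqueous electrodiffusion term.

    >>> born_energy(84e3) / 1e3
    66.0
    """
    if aqueous_term < 0:
        raise ValidationError("aqueous_term: must be >= 0")
    if activation_energy < aqueous_term:
        raise DomainError(
            "activation_energy below the aqueous term would imply a "
            "negative membrane barrier"
        )
    return activation_energy - aqueous_term


def partition_coefficient(born_energy: float, temperature: float) -> float:
    """Boltzmann partitioning of ions into the pore: exp(-W_B / R T)."""
    if not temperature > 0:
        raise ValidationError("temperature: must be > 0 kelvin")
    if born_energy < 0:
        raise ValidationError("born_energy: must be >= 0")
    return math.exp(-born_energy / (R_GAS * temperature))


def per_pore_conductance(
    gamma: float, spec: MembraneSpec, radius: float
) -> float:
    """Conductance of one partition-limited cylindrical aqueous pore.

    g = gamma * sigma * pi * r^2 / d — the ohmic conductance of an
    electrolyte cylinder of radius r spanning the bilayer thickness d,
    scaled by the ion partition coefficient.
    """
    if not radius > 0:
        raise ValidationError("radius: must be > 0")
    if gamma < 0:
        raise ValidationError("gamma: must be >= 0")
    return (gamma * spec.electrolyte_conductivity * math.pi * radius ** 2
            / spec.thickness)


def pore_density(g_membrane_specific: float, per_pore: float) -> float:
    """Areal pore count N = G_m(specific) / g(per pore)."""
    if g_membrane_specific < 0:
        raise ValidationError("g_membrane_specific: must be >= 0")
    if per_pore <= 0:
        raise DomainError(
            f"per_pore conductance must be > 0 to count pores "
            f"(got {per_pore!r}); check gamma and radius"
        )
    return g_membrane_specific / per_pore


# ---------------------------------------------------------------------------
# Barrier models (pluggable)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarrierModel:
    """A dielectric barrier W(r): molar energy of an ion mid-pore.

    Contract: W is strictly decreasing in radius and diverges as r -> 0.
    ``formula`` and ``citation`` document what the model computes.
    """

    name: str
    formula: str
    citation: str
    fn: Callable[[float, MembraneSpec], float] = field(repr=False)

    def __call__(self, radius, spec: MembraneSpec):
        if np.any(np.asarray(radius) <= 0):
            raise ValidationError("radius: must be > 0")
        return self.fn(radius, spec)


def _image_charge_barrier(radius: float, spec: MembraneSpec) -> float:
    # N_A q^2 / (4 pi e0 ew r) * (1 - em/ew) * lam / (lam + ew/em), lam = d/r.
    # The second factor is the dimensionless image-charge screening term:
    # -> 0 for a vanishing dielectric contrast or a short wide pore, -> its
    # contrast limit for a long narrow pore. Monotone decreasing in r.
    lam = spec.thickness / radius
    kappa = spec.eps_water / spec.eps_membrane
    self_energy = (spec.ion_charge ** 2
                   / (4.0 * math.pi * EPS0 * spec.eps_water * radius))
    f = (1.0 - spec.eps_membrane / spec.eps_water) * lam / (lam + kappa)
    return N_AVOGADRO * self_energy * f


_BARRIER_MODELS: Dict[str, BarrierModel] = {}


def register_barrier_model(model: BarrierModel) -> None:
    _BARRIER_MODELS[model.name] = model


def get_barrier_model(name: str) -> BarrierModel:
    try:
        return _BARRIER_MODELS[name]
    except KeyError:
        raise PresetLookupError(
            f"unknown barrier model {name!r}; registered models: "
            + ", ".join(sorted(_BARRIER_MODELS))
        ) from None


ImageChargeBarrier = BarrierModel(
    name="image-charge",
    formula=("W(r) = N_A q^2/(4 pi eps0 eps_w r) * (1 - eps_m/eps_w) "
             "* (d/r) / (d/r + eps_w/eps_m)"),
    citation=("Image-charge approximation for an ion centred in a "
              "water-filled cylindrical pore through a low-dielectric slab "
              "(dielectric-continuum treatment in the spirit of Parsegian, "
              "Nature 221:844, 1969)"),
    fn=_image_charge_barrier,
)
register_barrier_model(ImageChargeBarrier)


def pore_barrier(
    radius: float,
    spec: MembraneSpec,
    model: Union[str, BarrierModel] = "image-charge",
) -> float:
    """Molar dielectric barrier W(r) for the chosen model (J/mol)."""
    if isinstance(model, str):
        model = get_barrier_model(model)
    return model(radius, spec)


R_MIN_DEFAULT = 1e-12
R_MAX_DEFAULT = 1e-8


def invert_pore_radius(
    born_energy: float,
    spec: MembraneSpec,
    model: Union[str, BarrierModel] = "image-charge",
    r_min: float = R_MIN_DEFAULT,
    r_max: float = R_MAX_DEFAULT,
) -> float:
    """Radius at which the barrier model equals the measured Born energy.

    Bracketed root-find on [r_min, r_max]; unique because W(r) is strictly
    decreasing.  Converges to 1e-15 m absolute or 1e-9 relative, whichever
    binds first.
    """
    if isinstance(model, str):
        model = get_barrier_model(model)
    w_lo = model(r_max, spec)   # smallest attainable W
    w_hi = model(r_min, spec)   # largest attainable W
    if not w_lo <= born_energy <= w_hi:
        raise RangeError(
            f"Born energy {born_energy:.6g} J/mol outside attainable range "
            f"[W(r_max)={w_lo:.6g}, W(r_min)={w_hi:.6g}] for model "
            f"{model.name!r} on [{r_min:g}, {r_max:g}] m"
        )
    return float(brentq(lambda r: model(r, spec) - born_energy, r_min, r_max,
                        xtol=1e-15, rtol=1e-9))


def interfacial_free_energy(eq: LipidEquilibrium) -> float:
    """Bilayer surface free energy gamma_m from the monomer equilibrium.

    gamma_m = (mu_1,0 - mu_m,0 + k_B T ln X1) / a.  Negative values are
    physically suspect (they would favour unlimited monomer dissolution) and
    are returned as-is with a warning.
    """
    num = (eq.mu_monomer_std - eq.mu_bilayer_std
           + K_BOLTZMANN * eq.temperature * math.log(eq.mole_fraction_monomer))
    gamma_m = num / eq.area_per_molecule
    if gamma_m < 0:
        warnings.warn(
            "interfacial free energy is negative; check the standard "
            "chemical potentials and monomer mole fraction",
            stacklevel=2,
        )
    return gamma_m


def full_chain(
    activation_energy: float,
    g_membrane_specific: float,
    spec: MembraneSpec = MembraneSpec(),
    radius: Optional[float] = None,
    model: Union[str, BarrierModel] = "image-charge",
    aqueous_term: float = AQUEOUS_ELECTRODIFFUSION_EA,
) -> PoreProperties:
    """Activation energy -> Born energy -> partition -> pore properties.

    ``radius`` may be given directly (e.g. a reported value) or left None to
    invert it from the Born energy through the barrier model.  The returned
    record satisfies N * g = G_m(specific) by construction.
    """
    w_b = born_energy(activation_energy, aqueous_term)
    gamma = partition_coefficient(w_b, spec.temperature)
    r = radius if radius is not None else invert_pore_radius(w_b, spec, model)
    if not r > 0:
        raise ValidationError("radius: must be > 0")
    g = per_pore_conductance(gamma, spec, r)
    n = pore_density(g_membrane_specific, g)
    return PoreProperties(
        born_energy=w_b,
        partition_coefficient=gamma,
        pore_radius=r,
        per_pore_conductance=g,
        specific_pore_conductivity=g / spec.area,
        pore_density=n,
        membrane_conductance_specific=g_membrane_specific,
        activation_energy=activation_energy,
    )


def ea_uncertainty_factor(d_ea: float, temperature: float) -> float:
    """Multiplicative swing of the partition coefficient (and hence of the
    per-pore conductance and pore density) for an activation-energy
    uncertainty of +/- d_ea: exp(d_ea / R T)."""
    if not temperature > 0:
        raise ValidationError("temperature: must be > 0 kelvin")
    return math.exp(abs(d_ea) / (R_GAS * temperature))
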