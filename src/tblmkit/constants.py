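"""Physical constants and configurable defaults.

Every numeric constant the package uses lives here, so the pipeline can echo
each one exactly once into its provenance log.
"""

#: Molar gas constant, J/(mol K).
R_GAS = 8.314

#: Boltzmann constant, J/K.
K_BOLTZMANN = 1.380649e-23

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Elementary charge, C.
ELEMENTARY_CHARGE = 1.602176634e-19

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12

#: Celsius -> kelvin offset.
CELSIUS_OFFSET = 273.15

# ---------------------------------------------------------------------------
# Membrane / electrolyte defaults (config-overridable)
# ---------------------------------------------------------------------------

#: Relative permittivity of water at room temperature.
EPS_WATER = 80.0

#: Relative permittivity of the lipid hydrocarbon core.
EPS_MEMBRANE = 2.2

#: Conductivity of isotonic phosphate-buffered saline at room temperature, S/m.
SIGMA_PBS = 1.6

#: Gold working-electrode area of the six-electrode chip, m^2.
ELECTRODE_AREA = 2.1e-6

#: Lipid bilayer thickness, m.
BILAYER_THICKNESS = 5e-9

#: Room temperature (22 degC), K. Reference temperature for partitioning.
ROOM_TEMPERATURE = 295.15

#: Activation energy of electrodiffusion through the aqueous phase, J/mol.
#: Subtracted from the total Arrhenius activation energy to isolate the
#: membrane (Born) contribution.
AQUEOUS_ELECTRODIFFUSION_EA = 18e3

#: Specific capacitance above which a trace looks like a bare gold electrode
#: rather than a formed bilayer (warning threshold), F/m^2.
BARE_ELECTRODE_WARN_SPECIFIC_C = 50e-3
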