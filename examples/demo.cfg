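# Demo pipeline configuration: 10% xenon-saturated bilayer on a T10 chip.
# Run with:  tblm run --config examples/demo.cfg

[membrane]
area = 2.1e-6
thickness = 5e-9
electrolyte_conductivity = 1.6
temperature = 295.15

[protocol]
v_start = 0.0
v_max = 0.5
step_height = 5e-3
step_duration = 5e-5

[analysis]
onset_steps = 1
z_threshold = 5
aqueous_term_J_mol = 18e3
radius_m = 3e-11

[simulate]
scenario = xe10
thermal_scenario = thermal_xe10
seed = 1

[output]
directory = tblm_out
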