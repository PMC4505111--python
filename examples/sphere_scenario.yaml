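# Stimulated spherical cell, 1 ms — run with:
#   neurocable3d run examples/sphere_scenario.yaml --outdir results/sphere_run
scenario: sphere_demo
geometry:
  builder: sphere
  params:
    radius: 10.0
    extracellular_radius: 30.0
    resolution: 5.0
    subdivisions: 2
    stimulus_direction: [0.0, 0.0, 1.0]
    stimulus_angle_deg: 25.0
membrane:
  balanced_rest: true
  stimuli:
    - {cell: 0, amplitude: 2.0, t_on: 0.0, t_off: 0.5}
solver:
  dt: 0.01
  t_end: 1.0
sigma:
  intracellular: 2.0
  extracellular: 20.0
ephaptic: true
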