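# Example tonofem configuration (every field optional; defaults shown).
# Use with:  tonofem sweep --config docs/example_config.yaml --outdir out

geometry:
  corneal_anterior_radius: 7.75      # mm
  corneal_central_thickness: 0.52    # mm
  corneal_peripheral_thickness: 0.67 # mm
  scleral_radius: 11.2               # mm
  scleral_thickness: 0.317           # mm
  choroidal_thickness: 0.298         # mm
  axial_length: 22.7                 # mm
  junction_angle_superior: 178.1     # deg
  junction_angle_inferior: 177.7
  junction_angle_nasal: 173.9
  junction_angle_temporal: 177.0
  include_choroid_in_wall: false

materials:                           # E in MPa, density in kg/mm^3
  cornea: {young_modulus: 0.2, poisson_ratio: 0.43, density: 9.6e-7}
  sclera: {young_modulus: 2.0, poisson_ratio: 0.40, density: 9.6e-7}
  # the limbal junction band defaults to scleral properties; override with
  # junction: {young_modulus: ..., poisson_ratio: ...}

sweep:
  depths_mm: [0.3, 0.4, 0.5, 0.6, 0.7]   # probe plunging depths
  iops_mmhg: [10, 15, 20]                # intraocular pressures
  probes: [standard]                     # presets: standard (1.7 mm),
                                         # goldmann (3.06), validation (2.0);
                                         # or a diameter in mm

solver:
  resolution: reference                  # coarse | medium | reference
  constraint_mode: remote-rigid-body     # or posterior-patch
  n_increments: 10
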