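# Example end-to-end run: vehicle control plus three stimulation doses.
# Usage: shadowcyte all -c examples/run.yaml
seed: 1
output_dir: shadowcyte_out
optics:
  wavelength: 0.470          # um
  pinhole_diameter: 300.0    # um
  sample_to_sensor: 150.0    # um
  pixel_pitch: 2.2           # um
  sensor_shape: [384, 384]
  bit_depth: 8
profiling:
  n_angles: 36
  quorum: 8
analysis:
  control_label: vehicle
  lap_variant: ratio
simulate:
  n_cells: 150               # valid cells collected per group
  cells_per_image: 25
  groups:
    vehicle: 0.0             # activated fraction per cohort
    ASC25: 0.25
    ASC50: 0.5
    ASC100: 1.0
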