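analysis: {}
contact_area_um2: 40000.0
control:
  imaging_rate: 0.03333333333333333
  inner_rate: 2.0
  integral_gain: null
  mode: hold_position
  proportional_gain: 0.3
  setpoint: 0.0
  settling_tolerance: 0.05
  voltage_limits:
  - 0.0
  - 150.0
duration_s: 10800.0
force_target_nN: null
initial_voltage_V: null
loading_direction: assist
name: axial_stall
optics:
  background_level: 12000.0
  background_texture_amplitude: 150.0
  blur_scale: 1.5
  channel: brightfield
  density_contrast: 0.0
  field_of_view:
  - 96
  - 192
  frame_rate_max: 200.0
  imaging_depth: 20.0
  pixel_size: 0.5
  read_noise: 20.0
  shot_noise_scale: 0.3
  texture_seed: 1234
  tip_contrast: 8000.0
piezo:
  capacitor_coefficient: 900.0
  capacitor_gap: 100.0
  drift_rate: 0.01
  gain: 0.4
  readout_noise_capacitance: 0.002
  voltage_range:
  - 0.0
  - 150.0
probe:
  foil_height: 200.0
  foil_thickness: 15.0
  foil_width: 200.0
  label: none
  probe_length: 200.0
  spring_constant: 0.2
  tip_shape: foil
  tip_thickness: 15.0
  tip_width: 40.0
seeds:
  plant: 11
  sensor: 12
tip_sensor: synthetic
tip_sensor_noise_um: 0.05
tissue:
  active_stress_capacity: 100.0
  contact_mode: blocking
  dissipation_timescale: '.inf'
  free_velocity: 150.0
  passive_viscous_coefficient: 0.0
  yield_when_overloaded: false
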