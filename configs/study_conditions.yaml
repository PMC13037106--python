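particle:
  crystallite_diameter_nm: 5.8
  core_diameter_nm: 56.6
  shell_thickness_nm: 5.79
  packing_fraction: 0.62
  magnetite_density_g_cm3: 5.18
  saturation_magnetization_emu_g: 30.0
moment_mode: calibrated
force_calibration_points:
- - 3.25
  - 1.59e-05
- - 16.0
  - 0.000127
electromagnet:
  calibration_points:
  - - 1.0
    - 1.25
  - - 2.0
    - 2.25
  - - 3.0
    - 3.25
  operating_current_A: 3.0
ring_array:
  operating_gradient_T_per_m: 16.0
protocols:
  in_vitro:
    mode: cyclic
    on_duration_min: 15.0
    off_duration_min: 15.0
    total_span_h: 12.0
  in_vivo:
    mode: daily_sessions
    session_start_times:
    - 06:00
    - '12:00'
    - '18:00'
    session_duration_min: 15.0
    n_days: 14
measurements:
  cell_iron_pg: 2.05
  nerve_series:
    times_days:
    - 1.0
    - 3.0
    - 7.0
    - 14.0
    masses_ug:
    - 3.57
    - 2.13
    - 1.4
    - 0.34
seed: 0
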