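out_dir: runs/demo
seed: 7
phantom:
  baseline_radius: 4.0        # mm (8 mm vessel)
  elastic_modulus_true: 50.0  # mmHg per unit strain
  pressure_mean: 8.0          # mmHg
  pressure_amplitude: 2.0     # mmHg
  hysteresis_phase_lag: 0.2   # radians
  noise_sd_contour: 0.04      # mm (1% of radius)
cohort:
  n_animals: 7
stats:
  baseline: "0.0"
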