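# Demo pipeline configuration: a small synthetic senescence time course.
simulation:
  n_genes: 300
  frac_up: 0.1
  frac_down: 0.05
  time_points: [0, 3, 5, 7, 10, 12]
  n_bio_reps: 3
  n_tech_reps: 3
  biological_noise_sd: 0.1
  sample_scale_sd: 0.3
  cq_noise_sd: 0.15
  droplet_count_range: [14000, 17000]
  droplet_volume: 0.85
  seed: 42
screen:
  fc_threshold: 2.0
  p_threshold: 0.0005
  change_threshold: 0.20
  cv_threshold: 0.01
evaluate:
  targets: [ref_C, marker_up, marker_down]
  references: [ref_A, ref_B, ref_D, ref_E]
  scale_mode: per_replicate
background_correction: true
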