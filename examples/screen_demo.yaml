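# Screening demo: a well-normalized array study (small residual sample
# variation), where stable genes clear the strict CV_A filter.
simulation:
  n_genes: 1000
  frac_up: 0.05
  frac_down: 0.03
  biological_noise_sd: 0.02
  sample_scale_sd: 0.02
  up_fold_range_log2: [2.0, 4.0]
  down_fold_range_log2: [2.0, 4.0]
  seed: 7
screen:
  change_threshold: 0.20
  cv_threshold: 0.01
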