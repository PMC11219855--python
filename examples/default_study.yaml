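# Standard session: 6 x 71 ms segments, 70-cent stimulus noise clipped at
# +/- 2.2 SD; 150 pairs in 3 blocks of 50 with block 1 repeated in block 3.
seed: 1
stimulus:
  n_segments: 6
  segment_ms: 71.0
  noise_sd_cents: 70.0
  clip_sd: 2.2
  clip_mode: resample
design:
  n_blocks: 3
  block_size: 50
  repeat_source_block: 0
  repeat_target_block: 2
  n_repeats: 50
grid:
  sigma_max: 5.0
  sigma_step: 0.05
  criterion_bound: 3.0
  criterion_step: 0.05
  censor_threshold: 4.8
n_mc: 100000
observer:
  template: final_rise
  sigma_internal: 1.0
  criterion: 0.0
cohort:
  - {name: control, n: 21, template: final_rise, sigma_mean: 0.7, sigma_sd: 0.37}
  - {name: patient, n: 22, template: final_rise, sigma_mean: 2.54, sigma_sd: 1.90}
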