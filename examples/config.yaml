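# Default experiment configuration (all values shown are also the built-in
# defaults; delete blocks you do not want to override).
seed: 7
participants: {neutral: 8, aversive: 7, erotic: 6}
task:
  n_trials: 24
  n_training: 3
  first_cue_ms: 2000
geometry:
  distance_cm: 57.0
  screen_width_px: 1024
  screen_height_px: 768
  screen_width_cm: 44.7
  screen_height_cm: 33.5
preprocess:
  blink_pad_ms: 100.0
  pupil_smooth_window_ms: 100.0
  fixation_dispersion_deg: 4.0
  fixation_min_dur_ms: 100.0
detector:
  lambda_mult: 6.0
  min_dur_ms: 6.0
  merge_gap_ms: 20.0
  max_magnitude_deg: 1.0
ms_rate_dv: delta
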