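# Six-subject synthetic end-to-end demo (a few minutes on one CPU).
run_id: demo
seed: 1
stages:
  simulate: true
  preprocess: true
  windows: true
  pretrain: true
  train: true
  summarize: true
  evaluate: true
  wearsim: true
cohort:
  n_subjects: 6
  n_nights: 2
  time_in_bed_mean_hours: 1.2   # short nights keep the demo fast
  time_in_bed_sd_minutes: 10.0
  margin_hours: 0.5
sleepnet:
  preset: tiny
  max_epochs: 3
ssl:
  max_windows: 400
  epochs: 2
folds: 3
wearsim:
  n_subjects: 10
  hours_grid: [22, 24]
  days_grid: [3, 7]
  reps: 1
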