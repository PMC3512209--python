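# Default study configuration for `pitiming all --config configs/default.yaml`.
# Any omitted key falls back to the library default; unknown keys are rejected.
seed: 1
generator:
  criterion_T: 40.0      # reinforced interval, s
  pi_trial_factor: 3.0   # probe duration = factor x criterion
  n_fi: 20
  n_pi: 14
  n_pin: 6
  noise_onset_d2: 5.0    # s from trial onset
  noise_duration_d1: 5.0 # s
  start_frac: 0.7
  stop_frac: 1.4
  cv_start: 0.2
  cv_stop: 0.2
  rate_low: 0.1          # presses/s
  rate_high: 1.5
  p_no_control: 0.2
cohort:
  n_fear: 11
  n_ctrl: 6
  modes:                 # clock response to the distracter per group:drug
    "FEAR:SAL": over_reset
    "FEAR:NOM": over_reset
    "CTRL:SAL": run
    "CTRL:NOM": run
  salience:              # mean extra delay (s) beyond a full reset
    "FEAR:SAL": 8.0
    "FEAR:NOM": 3.0
    "CTRL:SAL": 0.0
    "CTRL:NOM": 0.0
analysis:
  bin_width: 4.0
  alpha: 0.05
  exclusion_f: 0.5
  tolerance: 2.0
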