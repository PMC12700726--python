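# Study-condition defaults for the synthetic night-monitoring generator.
# Hour axis runs 17:00 -> 05:00 (13 hour-blocks, wrapping midnight).

night_start: 17
night_end: 6
n_individuals: 24
n_nights: 30

audio:
  sample_rate: 48000       # Hz
  seconds_per_hour: 3600   # audio seconds per simulated hour-block
  aci_window_s: 600        # ACI analysis window
  frame_length: 1024       # STFT frame (samples)
  hop: 512
  noise_floor: 0.02        # Gaussian noise sd at zero wind
  wind_noise_coef: 0.008   # extra noise sd per m/s surface wind
  call:
    fundamental_hz: 650.0  # macaque-like pulsed harmonic stack
    n_harmonics: 6
    duration_s: 0.4
    amplitude: 0.3
    pulse_rate_hz: 12.0    # amplitude-modulation (pulse) rate
    pulse_duty: 0.5        # fraction of each pulse period that is voiced

# expected calls per hour-block; bimodal with peaks at 18-19 and 21-23,
# roughly 5x the late-night trough
hourly_rate: [8, 30, 28, 12, 26, 30, 22, 8, 6, 4, 3, 4, 6]

behavior_context:
  mean_context_behaviors: 2.0  # behaviors logged per vocal event
  aggression_peak_hour: 18     # aggression-heavy mix near this hour
  social_peak_hour: 21.5       # social-heavy mix near 21:00-22:00
  mix_width_h: 1.5
  mix_gain: 4.0

glmm:
  betas:        # per-individual count model, log link, z-scored predictors
    intercept: 7.748
    rank: -0.285
    sex: -1.909   # female = 1, male reference
    age: -1.342
    centrality: -2.163
    relatives: 0.249
  random_sd: 0.5

social:
  win_prob: 0.9              # chance the higher-ranked individual wins a bout
  interactions_per_dyad: 6.0
  family_size: 3
  focal_seconds: 36000.0
  within_kin_seconds: 3600.0  # mean co-proximity within a family
  between_kin_seconds: 300.0

weather:
  ar1: 0.8
  temperature: {mean: 5.0, sd: 4.0}     # deg C, winter nights
  humidity: {mean: 75.0, sd: 12.0}      # %
  precipitation: {scale: 1.5, threshold: 0.8}  # mm, mostly dry
  wind_sd: 2.0                           # m/s per component
  radiation_scale: 3.0                   # W/m^2, residual night radiation

coupling:       # planted weather -> ACI response (for recovery tests)
  base: 5.0
  meridional_amp: 2.0
  meridional_center: 1.0   # m/s
  meridional_width: 1.5
  temp_humidity_coef: -0.8 # on z-scales: low temp + high humidity raise ACI
  noise_sd: 0.3
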