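# Leptin-receptor-blocker-treated NZO cohort.
# (SBP, DBP) pairs give MAP 124.9 mmHg in the light phase and
# 127.9 mmHg in the dark phase.
name: alloaca-treated
seed: 20210703
duration_h: 48
bp_light_mean: [144.9, 114.9]
bp_dark_mean: [147.9, 117.9]
bp_circadian_amplitude: 3.0
bp_animal_sd: 7.0
hr_mean: 600.0
hr_circadian_delta: 30.0
hr_modulations:
  - [1.0, 0.04]
  - [2.5, 0.03]
hypnogram_params:
  mean_bout_s: {WAKE: 130.0, NREM: 170.0, REM: 55.0}
  p_nrem_to_rem: 0.26
apnea_rate: 33.7
desat_rate: 7.4
desat_depth: 6.0
spo2_baseline: 97.0
breath_params:
  WAKE: {v_t_ml: 0.35, rr_bpm: 150.0, duty_cycle: 0.40, ifl_fraction: 0.0}
  NREM: {v_t_ml: 0.30, rr_bpm: 90.7, duty_cycle: 0.30, ifl_fraction: 0.075}
  REM: {v_t_ml: 0.20, rr_bpm: 116.1, duty_cycle: 0.30, ifl_fraction: 0.193}
hvr_params:
  ve_normoxia_ml_min_g: 1.2
  ve_hypoxia_ml_min_g: 3.0
  spo2_normoxia: 97.0
  spo2_hypoxia: 63.0
  rr_normoxia_bpm: 120.0
  rr_hypoxia_bpm: 180.0
body_weight_g: 42.4
lights_on_hour: 9
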