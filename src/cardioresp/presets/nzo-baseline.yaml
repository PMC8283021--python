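# Untreated (control-peptide) NZO cohort at baseline.
# Blood-pressure pairs are (SBP, DBP) in mmHg chosen so that
# MAP = DBP + (SBP - DBP)/3 equals the group means: light 134.9,
# dark 137.5.  Breathing, apnea and desaturation parameters are the
# baseline group values; rates are events per hour of sleep.
name: nzo-baseline
seed: 20210702
duration_h: 48
bp_light_mean: [154.9, 124.9]
bp_dark_mean: [157.5, 127.5]
bp_circadian_amplitude: 3.0
bp_animal_sd: 7.0
hr_mean: 600.0
hr_circadian_delta: 30.0
hr_modulations:
  - [1.0, 0.04]
  - [2.5, 0.03]
hypnogram_params:
  mean_bout_s: {WAKE: 140.0, NREM: 150.0, REM: 60.0}
  p_nrem_to_rem: 0.32
apnea_rate: 31.4
desat_rate: 8.4
desat_depth: 6.0
spo2_baseline: 97.0
breath_params:
  WAKE: {v_t_ml: 0.35, rr_bpm: 150.0, duty_cycle: 0.40, ifl_fraction: 0.0}
  NREM: {v_t_ml: 0.30, rr_bpm: 107.5, duty_cycle: 0.27, ifl_fraction: 0.048}
  REM: {v_t_ml: 0.30, rr_bpm: 122.7, duty_cycle: 0.35, ifl_fraction: 0.183}
hvr_params:
  ve_normoxia_ml_min_g: 1.2
  ve_hypoxia_ml_min_g: 2.9
  spo2_normoxia: 97.0
  spo2_hypoxia: 63.0
  rr_normoxia_bpm: 120.0
  rr_hypoxia_bpm: 180.0
body_weight_g: 45.6
lights_on_hour: 9
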