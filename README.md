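# cardioresp

Cardiorespiratory and sleep phenotyping of rodent physiological signals:
blood-pressure telemetry, heart-rate-variability spectra, whole-body
plethysmography breathing, hypoxic ventilatory responses, and
EEG/EMG-based sleep staging with apnea and oxygen-desaturation scoring.

The package targets the analysis workflow of murine cardiovascular /
sleep-disordered-breathing studies (e.g. obese, hyperleptinemic strains
such as the New Zealand obese mouse): continuous 400 Hz arterial
pressure from implanted telemeters, 1000 Hz airflow from a barometric
plethysmograph combined with pulse oximetry, and 10-s-epoch
polysomnography. Because such studies rarely deposit raw recordings, a
first-class synthetic-signal generator (`cardioresp.synth`) produces
every input with known ground truth, so the complete pipeline is
testable offline.

## What it computes

* **`bp`** — per-beat systolic/diastolic detection from the pressure
  waveform, clock-aligned hourly means, and light/dark-phase summaries.
  MAP uses the one-third pulse-pressure rule, MAP = DBP + (SBP − DBP)/3.
* **`hrv`** — artifact filtering (readings <200 or >800 bpm removed and
  linearly interpolated), beat interval = 60/HR, 2-min Hamming windows
  overlapping by 1 min, periodograms aggregated into 0.1 Hz bins;
  LF = Σ power 0.4–1.5 Hz, HF = Σ power 1.6–4.0 Hz, and LF/HF.
* **`breaths`** — breath delineation from calibrated airflow (mL/s,
  inspiration positive): V_T (∫flow over inspiration), Ti, Ttot,
  RR = 60/Ttot, V_Imax, MIFR = V_T/Ti, duty cycle Ti/Ttot, minute
  ventilation V_E = V_T·RR normalized to body weight, and inspiratory
  flow-limitation flags (early flow plateau with rising effort).
* **`hvr`** — the hypoxic ventilatory response: ordinary least-squares
  slope of V_E (mL/min) on SpO2 (%) across a 5-min normoxic reference
  window and the 90-s hypoxic window \[onset+30 s, onset+120 s),
  reported positive and normalized by body weight (mL/min/g per %SpO2).
* **`sleep`** — rule-based 10-s-epoch staging (delta-dominant EEG + low
  EMG → NREM; theta-dominant low-amplitude EEG + atonia → REM; else
  WAKE), sleep architecture, apnea scoring (≥90 % airflow reduction for
  ≥2 breath cycles or ≥0.7 s during sleep), apnea index and ODI (≥5-point
  SpO2 drops) per hour of total sleep time.
* **`stats`** — two-sided Mann–Whitney U and Wilcoxon signed-rank tests
  (exact null for small samples without ties), Cohen's d, and tidy
  study-level reporting with group mean ± SEM.

## Worked example

```python
from cardioresp import synth, hvr, sleep, breaths

preset = synth.load_preset("nzo-baseline")

# hypoxic challenge: 20 min normoxia, 5 min 10% O2, body weight 42 g
rec = synth.gen_hvr_session(preset, body_weight_g=42.0, fs_flow=400.0)
res = hvr.compute_hvr(rec, hypoxia_onset_s=1200.0)
print(f"VE {res.ve_normoxia:.2f} -> {res.ve_hypoxia:.2f} mL/min/g, "
      f"HVR {res.hvr:.3f} mL/min/g/%")

# 6-h polysomnography with apneas at 31.4 events/h of sleep
psg = synth.gen_sleep_session(preset, fs_eeg=100.0, fs_flow=400.0,
                              fs_spo2=25.0)
hyp = sleep.score_epochs(psg["eeg"], psg["emg"])
arch = sleep.architecture(hyp)
events = sleep.detect_apneas(psg["flow"], hyp,
                             breaths=breaths.segment_breaths(psg["flow"]))
print(f"TST {arch.tst_min:.1f} min, NREM {arch.pct_nrem:.1f}%, "
      f"apnea index {sleep.apnea_index(events, arch):.1f}/h")
```

prints

```
VE 1.20 -> 2.89 mL/min/g, HVR 0.050 mL/min/g/%
TST 198.2 min, NREM 92.0%, apnea index 34.8/h
```

Ventilation roughly doubles while SpO2 falls from 97 % to 63 %, giving a
response slope of 0.050 mL/min/g per % desaturation; the scored apnea
burden recovers the preset's inserted rate (the exact index varies with
the Poisson draw of inserted events).

A command-line interface mirrors the library:
`cardioresp bp|hrv|breaths|hvr|psg|simulate --help`.

## Documentation

`docs/methods.md` describes the signal models, scoring rules, threshold
calibration, numerical choices and known limitations.
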