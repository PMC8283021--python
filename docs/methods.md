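# Methods

This note documents the models, scoring rules and numerical choices of
the package, and what the synthetic data do and do not establish.

## Signal containers

All channels are uniformly sampled `Trace`s (values, rate, units, clock
time of the first sample); a `Recording` bundles the traces of one
animal with group, body weight and the lighting schedule. Artifact
samples are carried as an explicit validity mask, never as sentinel
values. All time arithmetic runs in seconds from recording start;
clock time is used only to assign light (lights-on + 12 h) and dark
phases. EDF (16-bit, plain headers, one signal per channel) is the
polysomnography container; telemetry and single channels travel as
`time_s,value` CSV. The EDF codec is implemented in-package and is
cross-checked in the test suite against an independent reader (MNE);
EDF+ annotations and vendor telemetry formats are out of scope.

## Blood-pressure telemetry

Beats are detected on the pressure waveform by prominence-based peak
picking with a refractory period of 60/800 s (no beat above 800 bpm)
and a ~1 s prominence window; the diastolic value is the minimum
between consecutive systolic peaks. Hourly SBP/DBP are beat means over
clock-aligned hours; heart rate is beats per covered minute. MAP is
computed from the hourly means with the one-third pulse-pressure rule
MAP = DBP + (SBP − DBP)/3 — the conventional estimate when only
SBP/DBP summaries are retained. On the synthetic raised-cosine
waveform, the waveform-mean alternative differs by under 2 mmHg, so
the choice does not drive group comparisons. Hours without beats are
marked missing and excluded from phase means. Detection robustness to
real-world waveform pathology (damping, catheter artifacts,
arrhythmia) is out of scope.

## Heart-rate variability

The instantaneous heart-rate channel is cleaned by masking readings
strictly below 200 or above 800 bpm and filling them by linear
interpolation (edge runs take the nearest valid value); boundary
values are retained. The beat-to-beat interval is 60/HR, analysed as a
uniformly sampled signal, downsampled to 20 Hz (Nyquist 10 Hz, well
above the 4 Hz band ceiling). Two-minute segments overlapping by one
minute are mean-removed and Hamming-tapered; each one-sided
periodogram (native resolution 1/120 Hz) is aggregated into contiguous
0.1 Hz bins by summing raw-bin power, compensating the window's power
(mean of w²) so that total binned power equals the segment's variance
(Parseval; unit-tested to 1e-9 relative). A stated resolution of
0.1 Hz from 2-min windows is therefore interpreted as post-hoc binning,
not zero-padding.

Bins are labelled by their lower edge on the 0.1 Hz grid. LF sums the
bins labelled 0.4–1.5 Hz inclusive and HF the bins labelled 1.6–4.0 Hz
inclusive, so the 1.5–1.6 Hz bin belongs to LF and a modulation at
exactly 1.6 Hz lands in HF; a frequency sweep across the grid verifies
the band edges. Segment LF/HF values are averaged across segments and
the ratio is taken from the averages (ratio of averages, not average
of ratios). A zero HF average flags the ratio as undefined rather than
returning infinity. Powers are reported both in s² and ms²; the ratio
is unit-free.

One spectral subtlety: a line component sitting exactly on a bin edge
(e.g. 1.0 Hz) splits its Hamming side lobes across the edge, leaving
~87 % of its power in the labelled bin and ~13 % in the lower
neighbour; a mid-bin line concentrates ≥99 %. Band assignment is
unaffected because both fragments stay within the same band except at
the deliberate 1.5/1.6 boundary.

## Breath analysis

Airflow is assumed calibrated to mL/s with inspiration positive (as a
plethysmography system outputs after its own calibration); chamber
constants and humidity/temperature corrections are out of scope.
Breath onsets are negative-to-positive zero crossings of a 20 Hz
moving-average-smoothed copy, with hysteresis at 2 % of the running
amplitude to suppress noise-triggered micro-breaths; each onset is then
snapped to the raw-signal zero crossing so the rising edge of the
inspiration is not clipped. The inspiratory lobe is the positive run
containing the cycle's flow maximum (noise blips near the crossing are
thereby ignored); V_T integrates that lobe (trapezoid, zero-clipped
boundary samples included), Ti is its duration, V_Imax its maximum,
MIFR = V_T/Ti and DC = Ti/Ttot with Ttot the onset-to-onset interval.
Cycles outside 0.1–2 s (30–600 breaths/min) are rejected as artifacts.
An onset-to-onset delineator opens the first cycle at the first
crossing, so an N-cycle stationary record yields N−2 complete breaths.

Minute ventilation is the breath mean of V_T·60/Ttot, normalized by
body weight. Inspiratory flow limitation is flagged when flow reaches
95 % of V_Imax within the first 40 % of Ti, stays within ±5 % of the
peak for ≥40 % of Ti, and effort rises over the plateau (second-half
mean ≥5 % above first-half mean). The three thresholds quantify a
qualitative visual definition (early plateau with increasing effort)
and sit in `IFLConfig`; they are validated against synthetic clipped
breaths only.

## Hypoxic ventilatory response

The challenge protocol is 20 min of normoxia followed by 5 min of
hypoxia. The hypoxic analysis window is \[onset+30 s, onset+120 s) —
the first 30 s of gas exchange are excluded and the window ends at
2 min, when the response is dominated by the peripheral chemoreflex.
The normoxic reference is the final 5 min before the switch (quiet,
post-acclimation); the exact normoxic averaging window is a package
choice and is configurable. Per-breath V_E is paired with the nearest
SpO2 sample at the breath onset (no interpolation across the
transition), and the response is the OLS slope of V_E (mL/min) on SpO2
(%) over the pooled breaths of both windows, reported positive and
divided by body weight. A two-point regression on the window means is
available and coincides with the pooled fit for two equally weighted
clusters. Averaging across repeated challenge cycles is caller-side
arithmetic.

## Sleep staging and SDB scoring

Stages are scored in 10-s epochs. Per epoch the EEG delta (2–5 Hz) and
theta (5–10 Hz) band powers (Welch) and the EMG RMS are computed. NREM
requires delta/theta > 1.5 and EMG below the wake threshold; REM
requires theta/delta > 1.5 and EMG below the atonia threshold;
everything else is WAKE, and supra-threshold EMG forces WAKE regardless
of EEG. The two EMG thresholds are calibrated per recording from its
epoch EMG-RMS percentiles (midpoints of p50–p95 and p5–p50), which
makes a visual-scoring convention deterministic. This is an
operationalization, not a claim of equivalence with a human scorer;
the ≥90 % epoch agreement demonstrated on synthetic signals reflects
clean, strongly stage-coded EEG/EMG and will not transfer unchanged to
real recordings.

Architecture: TST = 10 s × (#NREM + #REM); NREM and REM percentages
are of TST; efficiency = TST / recording duration. Published rodent
tables sometimes imply a different duration denominator per animal;
this package always uses the actual recording duration and documents
the definition here.

Ventilation-analysis windows: every REM run, plus one 20-s window per
30-min block taken from the block's first run of ≥2 consecutive NREM
epochs — an automated stand-in for a manual once-per-30-min selection.

Apneas: breath amplitude for the reduction criterion is the peak of
the low-pass flow envelope over the inspiration (so waveform noise on
a near-silent breath cannot lift it past the threshold; the raw
V_Imax remains the reported metric), and the rolling baseline is the
median amplitude of the preceding 10 breaths. An event opens when
breath amplitude drops to ≤10 % of baseline (a ≥90 % reduction) or
the flow falls silent, and is
scored when it lasts ≥0.7 s or spans at least two local breath cycles
(2 × the median recent Ttot) — the two criteria are a disjunction.
Durations are quantized to breath boundaries, with a half-sample
tolerance on the comparisons. Events whose onset falls in a WAKE epoch
are discarded; the apnea index divides the count by TST. Events are
attributed to the stage at onset, and stage-stratified indices (still
over TST) are available alongside the overall index.

Desaturations: the baseline is a rolling 60-s median of SpO2
(computed on a ≤10 Hz working copy; desaturations evolve over tens of
seconds). An event opens when SpO2 falls ≥5 points below the baseline
(frozen at the crossing) and closes on recovery to within 2 points.
The 60-s window and the 2-point hysteresis are package choices held in
the function signature. ODI divides the event count by TST; mean SpO2
is reported separately over NREM and REM epochs.

## Synthetic data generator

The generator produces detector-faithful signals, not biophysically
realistic ones. Presets encode one study condition each; the shipped
`nzo-baseline` and `alloaca-treated` presets carry the group values of
an obese hypertensive mouse cohort at baseline and under leptin-receptor
blockade (light/dark MAP via SBP/DBP pairs under the one-third rule,
V_E plateaus of 1.2 and 2.9 mL/min/g, SpO2 97→63 %, stage-specific
breath shapes, 31.4 apneas per hour of sleep, body weights 45.6/42.4 g).

* **Pressure**: raised-cosine pulses between the DBP and SBP envelopes;
  the circadian modulation is cosine-phased so it integrates to zero
  over each 12-h phase, keeping phase means exactly at the preset
  values. Per-animal offsets are drawn Normal(0, 7 mmHg) — chosen so a
  5-animal cohort reproduces a group SEM near 3 mmHg, matching the
  between-animal spread typical of telemetered cohorts; this is an
  assumption, not a fitted quantity.
* **Heart rate**: beat interval (60/HR) modulated sinusoidally at the
  preset (frequency, depth) pairs; a single modulation places ≥90 % of
  off-DC interval power within ±0.1 Hz of its frequency. Artifacts are
  injected as 0.5-s excursions at caller-specified times/values.
* **Hypnogram**: semi-Markov bouts cycling WAKE → NREM → (REM with
  probability q) → WAKE with geometric bout lengths (means 140/150/60 s,
  q = 0.32), giving ≈54 % sleep, ≈11 % of sleep in REM and ≈22 min REM
  in 6 h.
* **Airflow**: per-breath half-sine inspiration (Ti = DC·Ttot) and a
  volume-balancing half-sine expiration; ±3 % cycle jitter. IFL breaths
  are clipped at 60 % of the unclipped peak over 20–80 % of Ti while
  the effort channel ramps up. Apneas are Poisson-placed over sleep at
  the preset rate; each replaces whole breaths (amplitude ×0.05, i.e. a
  ≥95 % reduction) spanning at least the drawn 0.8–2.0 s duration, and
  the ground-truth annotation snaps to the covered breath boundaries.
  Events require uninterrupted sleep from 20 s before to just after the
  event so detectors have a clean local baseline.
* **SpO2**: 97 % baseline with piecewise-linear desaturation dips of
  the preset depth (6 points) lasting 20–60 s, placed like apneas but
  with a 70-s lead-in and the whole dip inside sleep.
* **EEG/EMG**: per-stage narrow-band EEG (3.5 Hz dominant in NREM,
  7.5 Hz in REM, mixed low-amplitude in WAKE) and white-noise EMG with
  stage-coded RMS (60/20/4 µV); no attempt at realistic
  microarchitecture, arousals or transitions within epochs.

Default rates are 400 Hz for pressure and 1000 Hz for airflow/EEG/EMG,
matching common acquisition settings, and are configurable downward;
the test suite and the acceptance script run at 100–400 Hz, which the
breath and staging detectors resolve comfortably (≥30 samples per
inspiration, band ceilings ≤10 Hz). All randomness flows from one
seeded generator per call, keyed by the preset seed and an
operation-specific salt: identical (preset, seed) pairs are
bit-identical, and generated annotations are recoverable from the
signals by the pipeline's own detectors (verified in the suite).

What passing tests show: the pipeline recovers the parameters the
generator encoded, under clean signals whose noise levels (e.g.
0.05 mL/s flow noise, 1 mmHg pressure noise) are optimistic. They do
not show robustness to electrode artifacts, movement, chamber drift,
scorer disagreement or physiological nonstationarity.

## Statistics

Group comparisons use the two-sided Mann–Whitney U test (exact null
when min(n) ≤ 8 without ties, tie-corrected normal approximation
otherwise) and within-subject comparisons the two-sided Wilcoxon
signed-rank test (exact for ≤12 nonzero differences without tied
magnitudes; zero differences dropped). Exact p-values are verified
against full-enumeration oracles in the suite. Cohen's d is the mean
difference over the pooled SD. Mixed-effects regression is
intentionally not implemented: the report emits tidy per-animal rows
(CSV/JSON) formatted for external model fitting, and no multiple-testing
correction is applied.

## Acceptance quantities

`scripts/acceptance.py` recomputes, from scratch at each run: the
group-mean light-phase MAP of a simulated 5-animal, 48-h baseline
telemetry cohort (200 Hz); normoxic and hypoxic normalized V_E and the
HVR from one simulated challenge (400 Hz airflow, body weight 42 g);
and the apnea index as a group mean over seven simulated 6-h
polysomnograms — seven animals, matching the cohort size behind the
published group mean, which also tightens the Poisson sampling noise of
a single session. Sub-seeds for each quantity derive from `--seed` via
a seed sequence.

## Known limitations

* Stage scoring thresholds are percentile-calibrated per recording and
  assume all three states are present in non-trivial amounts.
* Apnea durations are breath-quantized; events shorter than one local
  cycle cannot be represented.
* The desaturation baseline ignores the sleep/wake state of the
  preceding 60 s (events themselves are gated to sleep).
* The EDF writer requires integer sampling rates and equal-duration
  channels — true for all signals this package produces.
* Real-data robustness (artifact rejection beyond the stated rules) is
  explicitly out of scope.
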