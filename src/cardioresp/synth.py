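"""Synthetic cardiorespiratory signal generator with ground truth.

Every input the analysis pipeline consumes — arterial-pressure telemetry,
heart-rate series, polysomnography (EEG/EMG/airflow/effort/SpO2) and
normoxia→hypoxia challenges — can be generated here from a
:class:`SynthPreset`, together with the ground-truth annotations
(hypnogram, event list, hourly blood pressure, ventilatory-response slope)
needed to test the downstream detectors.

Signal models are deliberately simple but detector-faithful:

* arterial pressure: per-beat raised-cosine pulse between the diastolic
  and systolic envelope, with a smooth circadian modulation whose mean
  vanishes over each 12-h lighting phase, plus per-animal random offsets;
* airflow: per-breath half-sine inspiration (``Ti = DC * Ttot``) and a
  volume-balancing half-sine expiration; flow-limited breaths are
  amplitude-clipped over the middle 20–80 % of inspiration while the
  effort channel keeps rising;
* apneas: breath amplitude scaled to 5 % of baseline for the drawn
  duration (a ≥90 % reduction), inserted as a Poisson process over sleep;
* SpO2: piecewise-linear desaturation dips from a 97 % baseline;
* EEG/EMG: per-stage narrow-band amplitude and muscle tone, driven by a
  semi-Markov bout hypnogram in 10-s epochs.

All randomness flows from one seeded generator per call; identical
(preset, seed) pairs give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .core import Recording, Trace

__all__ = [
    "StageBreathing",
    "SynthPreset",
    "load_preset",
    "available_presets",
    "gen_bp_telemetry",
    "gen_hr_series",
    "gen_sleep_session",
    "gen_hvr_session",
]

EPOCH_S = 10.0
STAGES = ("WAKE", "NREM", "REM")


@dataclass
class StageBreathing:
    """Breathing pattern of one vigilance state."""

    v_t_ml: float
    rr_bpm: float
    duty_cycle: float
    ifl_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (self.v_t_ml > 0 and self.rr_bpm > 0):
            raise ValueError("tidal volume and respiratory rate must be > 0")
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty cycle must lie in (0, 1)")
        if not 0 <= self.ifl_fraction <= 1:
            raise ValueError("IFL fraction must lie in [0, 1]")


@dataclass
class SynthPreset:
    """Parameter bundle describing one simulated study condition.

    Blood-pressure means are (SBP, DBP) pairs in mmHg per lighting
    phase; ``hvr_params`` holds body-weight-normalized minute
    ventilation (mL/min/g) and SpO2 plateaus (%) for the normoxic and
    hypoxic steady states; ``hypnogram_params`` holds mean bout lengths
    (s) per stage and the NREM→REM transition probability that together
    set the stage fractions.
    """

    name: str
    seed: int
    duration_h: float = 48.0
    bp_light_mean: tuple[float, float] = (154.9, 124.9)
    bp_dark_mean: tuple[float, float] = (157.5, 127.5)
    bp_circadian_amplitude: float = 3.0
    bp_animal_sd: float = 7.0
    hr_mean: float = 600.0
    hr_circadian_delta: float = 30.0
    hr_modulations: list[tuple[float, float]] = field(default_factory=list)
    hypnogram_params: dict = field(
        default_factory=lambda: {
            "mean_bout_s": {"WAKE": 140.0, "NREM": 150.0, "REM": 60.0},
            "p_nrem_to_rem": 0.32,
        }
    )
    apnea_rate: float = 0.0  # events per hour of sleep
    apnea_duration_s: tuple[float, float] = (0.8, 2.0)
    desat_rate: float = 0.0  # events per hour of sleep
    desat_depth: float = 6.0  # percentage points below baseline
    spo2_baseline: float = 97.0
    breath_params: dict[str, StageBreathing] = field(
        default_factory=lambda: {
            "WAKE": StageBreathing(0.35, 150.0, 0.40, 0.0),
            "NREM": StageBreathing(0.30, 107.5, 0.27, 0.05),
            "REM": StageBreathing(0.30, 122.7, 0.35, 0.18),
        }
    )
    ifl_clip_fraction: float = 0.6
    hvr_params: dict = field(
        default_factory=lambda: {
            "ve_normoxia_ml_min_g": 1.2,
            "ve_hypoxia_ml_min_g": 2.9,
            "spo2_normoxia": 97.0,
            "spo2_hypoxia": 63.0,
            "rr_normoxia_bpm": 120.0,
            "rr_hypoxia_bpm": 180.0,
        }
    )
    body_weight_g: float = 45.6
    lights_on_hour: float = 9.0
    noise_sd: dict = field(
        default_factory=lambda: {
            "bp": 1.0, "hr": 1.0, "flow": 0.05, "eeg": 10.0,
            "emg": 0.0, "spo2": 0.15,
        }
    )

    def __post_init__(self) -> None:
        if isinstance(self.bp_light_mean, list):
            self.bp_light_mean = tuple(self.bp_light_mean)
        if isinstance(self.bp_dark_mean, list):
            self.bp_dark_mean = tuple(self.bp_dark_mean)
        for k, v in list(self.breath_params.items()):
            if isinstance(v, dict):
                self.breath_params[k] = StageBreathing(**v)
        self.hr_modulations = [tuple(m) for m in self.hr_modulations]
        if not self.duration_h > 0:
            raise ValueError("duration_h must be positive")
        if not self.hr_mean > 0:
            raise ValueError("hr_mean must be positive")
        for sbp, dbp in (self.bp_light_mean, self.bp_dark_mean):
            if sbp <= dbp:
                raise ValueError("systolic must exceed diastolic")
        if self.apnea_rate < 0:
            raise ValueError("apnea_rate must be non-negative")
        if self.desat_rate < 0:
            raise ValueError("desat_rate must be non-negative")
        if self.desat_depth < 0:
            raise ValueError("desat_depth must be non-negative")
        if not 0 < self.spo2_baseline <= 100:
            raise ValueError("spo2_baseline must lie in (0, 100]")
        for key in ("spo2_normoxia", "spo2_hypoxia"):
            if not 0 < self.hvr_params[key] <= 100:
                raise ValueError(f"{key} must lie in (0, 100]")
        if not self.body_weight_g > 0:
            raise ValueError("body_weight_g must be positive")
        for f, depth in self.hr_modulations:
            if depth >= 1:
                raise ValueError(
                    "heart-rate modulation depth must be < 1 "
                    "(beat intervals would go non-positive)"
                )
        if self.seed is None:
            raise ValueError("presets require an explicit seed")

    def stage_fractions(self) -> dict[str, float]:
        """Expected long-run stage fractions implied by the bout model.

        The hypnogram cycles WAKE → NREM → (REM with probability q) →
        WAKE, so expected time per cycle is the mean bout length for
        WAKE and NREM and q times the mean REM bout.
        """
        mb = self.hypnogram_params["mean_bout_s"]
        q = self.hypnogram_params["p_nrem_to_rem"]
        w, n, r = mb["WAKE"], mb["NREM"], q * mb["REM"]
        tot = w + n + r
        return {"WAKE": w / tot, "NREM": n / tot, "REM": r / tot}

    def replace(self, **kwargs) -> "SynthPreset":
        return dataclasses.replace(self, **kwargs)


def available_presets() -> list[str]:
    root = resources.files("cardioresp") / "presets"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def load_preset(name: str, **overrides) -> SynthPreset:
    """Load a named preset from the packaged YAML library."""
    path = resources.files("cardioresp") / "presets" / f"{name}.yaml"
    try:
        payload = yaml.safe_load(path.read_text())
    except FileNotFoundError as exc:
        raise KeyError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from exc
    payload.update(overrides)
    return SynthPreset(**payload)


def _rng(preset: SynthPreset, salt: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([preset.seed % (2**31), salt, extra])


# ---------------------------------------------------------------------------
# Blood-pressure telemetry
# ---------------------------------------------------------------------------

def _bp_envelope(preset: SynthPreset, clock_s: np.ndarray,
                 offset: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (SBP, DBP) envelope in mmHg at the given clock times.

    The circadian term is a sinusoid phased so that its mean over each
    12-h lighting phase is zero, which keeps the phase means equal to
    the preset values exactly.
    """
    hour = (clock_s / 3600.0) % 24.0
    light = ((hour - preset.lights_on_hour) % 24.0) < 12.0
    sbp = np.where(light, preset.bp_light_mean[0], preset.bp_dark_mean[0])
    dbp = np.where(light, preset.bp_light_mean[1], preset.bp_dark_mean[1])
    # cosine phasing: the modulation integrates to zero over each 12-h
    # phase, so phase means equal the preset values exactly
    circ = preset.bp_circadian_amplitude * np.cos(
        2 * np.pi * (hour - preset.lights_on_hour) / 24.0
    )
    return sbp + circ + offset, dbp + circ + offset


def gen_bp_telemetry(preset: SynthPreset, n_animals: int,
                     fs: float = 400.0,
                     start_clock_h: float = 9.0) -> list[Recording]:
    """Simulate arterial-pressure telemetry for a cohort.

    Each animal gets a ``duration_h``-long 400 Hz (default) pressure
    waveform built from raised-cosine pulses between its diastolic and
    systolic envelope, plus a ground-truth hourly SBP/DBP/MAP table in
    ``annotations["hourly_bp"]``.
    """
    if not preset.duration_h >= 1:
        raise ValueError("telemetry generation requires duration >= 1 h")
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    n = int(round(preset.duration_h * 3600 * fs))
    start_s = start_clock_h * 3600.0
    out = []
    for a in range(n_animals):
        rng = _rng(preset, 101, a)
        offset = rng.normal(0.0, preset.bp_animal_sd)
        # envelopes and heart rate vary on circadian time scales: build
        # them on a 1-s grid and repeat to the sampling rate
        sec = int(round(preset.duration_h * 3600))
        clock1 = start_s + np.arange(sec, dtype=float)
        hour1 = (clock1 / 3600.0) % 24.0
        hr1 = preset.hr_mean - preset.hr_circadian_delta * np.sin(
            2 * np.pi * (hour1 - preset.lights_on_hour) / 24.0
        )
        sbp1, dbp1 = _bp_envelope(preset, clock1, offset)
        reps = int(round(fs))
        hr = np.repeat(hr1, reps)[:n]
        phase = np.cumsum(hr / 60.0) / fs
        del hr
        pulse = 0.5 * (1.0 - np.cos(2 * np.pi * phase))
        del phase
        dbp_env = np.repeat(dbp1, reps)[:n]
        p = dbp_env + np.repeat(sbp1 - dbp1, reps)[:n] * pulse
        del pulse, dbp_env
        sd = preset.noise_sd.get("bp", 0.0)
        if sd > 0:
            p = p + rng.normal(0.0, sd, size=n)
        # ground truth: hourly envelope means on a 1-min grid
        hours = int(preset.duration_h)
        tm = start_s + np.arange(hours * 60) * 60.0 + 30.0
        sb, db = _bp_envelope(preset, tm, offset)
        hourly = []
        for h in range(hours):
            s = float(np.mean(sb[h * 60:(h + 1) * 60]))
            d = float(np.mean(db[h * 60:(h + 1) * 60]))
            hourly.append({
                "hour_index": h,
                "clock_hour": (start_clock_h + h) % 24.0,
                "sbp": s, "dbp": d, "map": d + (s - d) / 3.0,
            })
        rec = Recording(
            animal_id=f"{preset.name}-{a:02d}",
            group="treated" if "treat" in preset.name else "control",
            body_weight_g=preset.body_weight_g,
            lights_on_hour=preset.lights_on_hour,
        )
        rec.traces["pressure"] = Trace(
            "pressure", p.astype(np.float64), fs, "mmHg", start_s
        )
        rec.annotations = {
            "hourly_bp": hourly,
            "animal_offset_mmhg": float(offset),
            "phase_truth": {
                "light_map": (preset.bp_light_mean[1]
                              + (preset.bp_light_mean[0]
                                 - preset.bp_light_mean[1]) / 3.0),
                "dark_map": (preset.bp_dark_mean[1]
                             + (preset.bp_dark_mean[0]
                                - preset.bp_dark_mean[1]) / 3.0),
            },
        }
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Heart-rate series
# ---------------------------------------------------------------------------

def gen_hr_series(preset: SynthPreset,
                  artifact_spec: list[tuple[float, float]] | None = None,
                  duration_s: float = 600.0, fs: float = 100.0,
                  artifact_duration_s: float = 0.5) -> Trace:
    """Instantaneous heart-rate channel with beat-interval modulation.

    The beat interval is ``(60 / hr_mean) * (1 + sum depth*sin(2*pi*f*t))``
    so a single modulation shows up as a single off-DC line in the
    interval spectrum.  Artifacts from ``artifact_spec`` (time s, value
    bpm) overwrite the clean trace for ``artifact_duration_s`` and may
    deliberately violate the physiological 200–800 bpm range.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    rng = _rng(preset, 202)
    t = np.arange(int(round(duration_s * fs))) / fs
    interval = np.full(t.size, 60.0 / preset.hr_mean)
    base = 60.0 / preset.hr_mean
    for f, depth in preset.hr_modulations:
        interval = interval + base * depth * np.sin(2 * np.pi * f * t)
    hr = 60.0 / interval
    sd = preset.noise_sd.get("hr", 0.0)
    if sd > 0:
        hr = hr + rng.normal(0.0, sd, size=hr.size)
    for at, av in (artifact_spec or []):
        i0 = int(round(at * fs))
        i1 = min(hr.size, i0 + max(1, int(round(artifact_duration_s * fs))))
        if 0 <= i0 < hr.size:
            hr[i0:i1] = av
    return Trace("heart_rate", hr, fs, "bpm")


# ---------------------------------------------------------------------------
# Hypnogram and polysomnography
# ---------------------------------------------------------------------------

def _gen_hypnogram(preset: SynthPreset, n_epochs: int,
                   rng: np.random.Generator) -> list[str]:
    """Semi-Markov bout hypnogram: WAKE → NREM → (REM | WAKE) → WAKE."""
    mb = preset.hypnogram_params["mean_bout_s"]
    q = preset.hypnogram_params["p_nrem_to_rem"]
    stages: list[str] = []
    stage = "WAKE"
    while len(stages) < n_epochs:
        mean_ep = max(1.0, mb[stage] / EPOCH_S)
        # geometric bout length with the requested mean, minimum 1 epoch
        bout = 1 + rng.geometric(1.0 / mean_ep) - 1 if mean_ep > 1 else 1
        bout = max(1, min(int(bout), n_epochs - len(stages)))
        stages.extend([stage] * bout)
        if stage == "WAKE":
            stage = "NREM"
        elif stage == "NREM":
            stage = "REM" if rng.random() < q else "WAKE"
        else:
            stage = "WAKE"
    return stages[:n_epochs]


def _draw_events(rng: np.random.Generator, stages: list[str],
                 rate_per_h: float, dur_lo: float, dur_hi: float,
                 min_gap_s: float, lead_in_s: float) -> list[dict]:
    """Poisson-place events inside sleep, each preceded by stable sleep.

    ``lead_in_s`` of uninterrupted sleep is required before an event so
    detectors have a clean local baseline; events are separated by at
    least ``min_gap_s``.
    """
    sleep = np.array([s != "WAKE" for s in stages])
    tst_h = sleep.sum() * EPOCH_S / 3600.0
    n_events = rng.poisson(rate_per_h * tst_h) if rate_per_h > 0 else 0
    if n_events == 0:
        return []
    drawn: list[tuple[float, float]] = []
    attempts = 0
    while len(drawn) < n_events and attempts < 200 * n_events + 200:
        attempts += 1
        dur = float(rng.uniform(dur_lo, dur_hi))
        ep = int(rng.integers(0, len(stages)))
        t0 = ep * EPOCH_S + rng.uniform(0.0, EPOCH_S - 0.5)
        # the whole event span, a lead-in for detector baselines and a
        # short tail must lie in uninterrupted sleep
        e0 = int((t0 - lead_in_s) // EPOCH_S)
        e1 = int((t0 + dur + 2.0) // EPOCH_S)
        if e0 < 0 or e1 >= len(stages) or not sleep[e0:e1 + 1].all():
            continue
        if any(abs(t0 - s) < min_gap_s for s, _ in drawn):
            continue
        drawn.append((t0, dur))
    return [
        {"start_s": t0, "duration_s": dur,
         "stage": stages[int(t0 // EPOCH_S)]}
        for t0, dur in sorted(drawn)
    ]


def _render_breaths(preset: SynthPreset, stages: list[str], fs: float,
                    rng: np.random.Generator,
                    rr_jitter: float = 0.03) -> tuple[np.ndarray, np.ndarray,
                                                      list[dict]]:
    """Breath-by-breath airflow (+ effort surrogate) for a hypnogram."""
    n = int(round(len(stages) * EPOCH_S * fs))
    flow = np.zeros(n)
    effort = np.zeros(n)
    breaths = []
    t = 0.0
    total_s = len(stages) * EPOCH_S
    while t < total_s - 0.05:
        stage = stages[min(len(stages) - 1, int(t // EPOCH_S))]
        bp = preset.breath_params[stage]
        ttot = 60.0 / bp.rr_bpm * (1.0 + rng.normal(0.0, rr_jitter))
        ttot = float(np.clip(ttot, 0.15, 1.9))
        ti = bp.duty_cycle * ttot
        te = ttot - ti
        is_ifl = stage != "WAKE" and rng.random() < bp.ifl_fraction
        i0 = int(round(t * fs))
        n_i = max(2, int(round(ti * fs)))
        n_e = max(2, int(round(te * fs)))
        if i0 + n_i + n_e > n:
            break
        ti_eff = n_i / fs
        amp = np.pi * bp.v_t_ml / (2.0 * ti_eff)
        tt = np.arange(n_i) / fs
        insp = amp * np.sin(np.pi * tt / ti_eff)
        eff = insp.copy()
        if is_ifl:
            cap = preset.ifl_clip_fraction * amp
            window = (tt >= 0.2 * ti_eff) & (tt <= 0.8 * ti_eff)
            insp = np.where(window, np.minimum(insp, cap), insp)
            eff = eff * (1.0 + 0.8 * tt / ti_eff)  # drive keeps rising
        v_actual = float(np.trapezoid(insp, dx=1.0 / fs))
        te_eff = n_e / fs
        amp_e = np.pi * v_actual / (2.0 * te_eff)
        expv = -amp_e * np.sin(np.pi * np.arange(n_e) / fs / te_eff)
        flow[i0:i0 + n_i] = insp
        flow[i0 + n_i:i0 + n_i + n_e] = expv
        effort[i0:i0 + n_i] = eff
        breaths.append({
            "onset_s": i0 / fs, "ti_s": ti_eff, "ttot_s": (n_i + n_e) / fs,
            "v_t_ml": v_actual, "stage": stage, "ifl": bool(is_ifl),
        })
        t = (i0 + n_i + n_e) / fs
    return flow, effort, breaths


def gen_sleep_session(preset: SynthPreset, duration_h: float = 6.0,
                      fs_eeg: float = 1000.0, fs_flow: float = 1000.0,
                      fs_spo2: float = 100.0,
                      start_clock_h: float = 10.0) -> Recording:
    """Simulate one polysomnography session.

    Returns a :class:`Recording` with ``eeg``, ``emg``, ``flow``,
    ``effort`` and ``spo2`` traces; the ground-truth hypnogram, apnea
    and desaturation events and per-breath table live in
    ``annotations``.
    """
    if preset.apnea_rate < 0:
        raise ValueError("apnea_rate must be non-negative")
    n_epochs = int(duration_h * 3600 / EPOCH_S)
    rng = _rng(preset, 303)
    stages = _gen_hypnogram(preset, n_epochs, rng)

    apneas = _draw_events(rng, stages, preset.apnea_rate,
                          preset.apnea_duration_s[0],
                          preset.apnea_duration_s[1],
                          min_gap_s=25.0, lead_in_s=20.0)
    desats = _draw_events(rng, stages, preset.desat_rate,
                          20.0, 60.0, min_gap_s=120.0, lead_in_s=70.0)

    flow, effort, breaths = _render_breaths(preset, stages, fs_flow, rng)
    # apneas replace whole breaths (amplitude scaled to 5 %, a ≥90 %
    # reduction); ground truth snaps to the covered breath boundaries
    onsets = np.array([b["onset_s"] for b in breaths])
    ends = np.array([b["onset_s"] + b["ttot_s"] for b in breaths])
    for ev in apneas:
        t0, t1 = ev["start_s"], ev["start_s"] + ev["duration_s"]
        covered = np.flatnonzero((ends > t0) & (onsets < t1))
        if covered.size == 0:
            continue
        a0, a1 = float(onsets[covered[0]]), float(ends[covered[-1]])
        i0 = int(round(a0 * fs_flow))
        i1 = int(round(a1 * fs_flow))
        flow[i0:i1] *= 0.05
        ev["start_s"], ev["duration_s"] = a0, a1 - a0
        ev["stage"] = stages[min(len(stages) - 1, int(a0 // EPOCH_S))]
    sd = preset.noise_sd.get("flow", 0.0)
    if sd > 0:
        flow = flow + rng.normal(0.0, sd, size=flow.size)

    # EEG: stage-coded narrow bands; WAKE is low-amplitude mixed content
    n_eeg = int(round(n_epochs * EPOCH_S * fs_eeg))
    t_eeg = np.arange(n_eeg) / fs_eeg
    eeg = np.zeros(n_eeg)
    emg = np.zeros(n_eeg)
    eeg_amp = {"WAKE": (50.0, 50.0), "NREM": (300.0, 30.0),
               "REM": (20.0, 120.0)}  # (delta-band 3.5 Hz, theta-band 7.5 Hz)
    emg_rms = {"WAKE": 60.0, "NREM": 20.0, "REM": 4.0}
    spe = int(EPOCH_S * fs_eeg)
    emg_noise = rng.normal(0.0, 1.0, size=n_eeg)
    for e, stage in enumerate(stages):
        sl = slice(e * spe, (e + 1) * spe)
        a_d, a_t = eeg_amp[stage]
        eeg[sl] = (a_d * np.sin(2 * np.pi * 3.5 * t_eeg[sl])
                   + a_t * np.sin(2 * np.pi * 7.5 * t_eeg[sl]))
        emg[sl] = emg_rms[stage] * emg_noise[sl]
    sd = preset.noise_sd.get("eeg", 0.0)
    if sd > 0:
        eeg = eeg + rng.normal(0.0, sd, size=n_eeg)

    # SpO2 with piecewise-linear desaturation dips
    n_sp = int(round(n_epochs * EPOCH_S * fs_spo2))
    spo2 = np.full(n_sp, preset.spo2_baseline)
    for ev in desats:
        i0 = int(round(ev["start_s"] * fs_spo2))
        nd = int(round(ev["duration_s"] * fs_spo2))
        down, up = int(0.3 * nd), int(0.3 * nd)
        plateau = nd - down - up
        dip = np.concatenate([
            np.linspace(0.0, preset.desat_depth, down, endpoint=False),
            np.full(plateau, preset.desat_depth),
            np.linspace(preset.desat_depth, 0.0, up),
        ])
        i1 = min(n_sp, i0 + dip.size)
        spo2[i0:i1] -= dip[: i1 - i0]
    sd = preset.noise_sd.get("spo2", 0.0)
    if sd > 0:
        spo2 = spo2 + rng.normal(0.0, sd, size=n_sp)
    np.clip(spo2, 0.0, 100.0, out=spo2)

    start_s = start_clock_h * 3600.0
    rec = Recording(
        animal_id=f"{preset.name}-psg",
        group="treated" if "treat" in preset.name else "control",
        body_weight_g=preset.body_weight_g,
        lights_on_hour=preset.lights_on_hour,
    )
    rec.traces["eeg"] = Trace("eeg", eeg, fs_eeg, "uV", start_s)
    rec.traces["emg"] = Trace("emg", emg, fs_eeg, "uV", start_s)
    rec.traces["flow"] = Trace("flow", flow, fs_flow, "mL/s", start_s)
    rec.traces["effort"] = Trace("effort", effort, fs_flow, "au", start_s)
    rec.traces["spo2"] = Trace("spo2", spo2, fs_spo2, "%", start_s)
    events = (
        [dict(type="APNEA", **ev) for ev in apneas]
        + [dict(type="DESAT", **ev) for ev in desats]
    )
    rec.annotations = {
        "epoch_len_s": EPOCH_S,
        "hypnogram": stages,
        "events": sorted(events, key=lambda ev: ev["start_s"]),
        "breaths": breaths,
    }
    return rec


# ---------------------------------------------------------------------------
# Hypoxic-challenge session
# ---------------------------------------------------------------------------

def gen_hvr_session(preset: SynthPreset, body_weight_g: float | None = None,
                    fs_flow: float = 1000.0, fs_spo2: float = 100.0,
                    normoxia_s: float = 1200.0, hypoxia_s: float = 300.0,
                    transition_s: float = 30.0) -> Recording:
    """Simulate a normoxia→hypoxia challenge in the plethysmograph.

    20 min of normoxic breathing are followed by 5 min of hypoxia;
    minute ventilation and SpO2 ramp to their hypoxic plateaus within
    ``transition_s`` of the gas switch.  The ground-truth
    body-weight-normalized slope of VE against SpO2 is attached in
    ``annotations["hvr_truth"]``.
    """
    hp = preset.hvr_params
    bw = preset.body_weight_g if body_weight_g is None else body_weight_g
    if not bw > 0:
        raise ValueError("body weight must be positive")
    rng = _rng(preset, 404)
    onset = normoxia_s
    total = normoxia_s + hypoxia_s

    def ramp(t: float, a: float, b: float) -> float:
        if t < onset:
            return a
        if t >= onset + transition_s:
            return b
        return a + (b - a) * (t - onset) / transition_s

    ve_n = hp["ve_normoxia_ml_min_g"] * bw  # mL/min
    ve_h = hp["ve_hypoxia_ml_min_g"] * bw
    n = int(round(total * fs_flow))
    flow = np.zeros(n)
    t = 0.0
    dc = preset.breath_params["WAKE"].duty_cycle
    while t < total - 0.05:
        rr = ramp(t, hp["rr_normoxia_bpm"], hp["rr_hypoxia_bpm"])
        ve = ramp(t, ve_n, ve_h)
        v_t = ve / rr  # mL per breath
        ttot = 60.0 / rr * (1.0 + rng.normal(0.0, 0.02))
        i0 = int(round(t * fs_flow))
        n_i = max(2, int(round(dc * ttot * fs_flow)))
        n_e = max(2, int(round((1 - dc) * ttot * fs_flow)))
        if i0 + n_i + n_e > n:
            break
        ti_eff = n_i / fs_flow
        amp = np.pi * v_t / (2.0 * ti_eff)
        flow[i0:i0 + n_i] = amp * np.sin(
            np.pi * np.arange(n_i) / fs_flow / ti_eff)
        te_eff = n_e / fs_flow
        amp_e = np.pi * v_t / (2.0 * te_eff)
        flow[i0 + n_i:i0 + n_i + n_e] = -amp_e * np.sin(
            np.pi * np.arange(n_e) / fs_flow / te_eff)
        t = (i0 + n_i + n_e) / fs_flow
    sd = preset.noise_sd.get("flow", 0.0)
    if sd > 0:
        flow = flow + rng.normal(0.0, sd, size=n)

    n_sp = int(round(total * fs_spo2))
    t_sp = np.arange(n_sp) / fs_spo2
    spo2 = np.array([ramp(tt, hp["spo2_normoxia"], hp["spo2_hypoxia"])
                     for tt in t_sp])
    sd = preset.noise_sd.get("spo2", 0.0)
    if sd > 0:
        spo2 = spo2 + rng.normal(0.0, sd, size=n_sp)
    np.clip(spo2, 0.0, 100.0, out=spo2)

    slope_norm = ((hp["ve_hypoxia_ml_min_g"] - hp["ve_normoxia_ml_min_g"])
                  / (hp["spo2_normoxia"] - hp["spo2_hypoxia"]))
    rec = Recording(
        animal_id=f"{preset.name}-hvr",
        group="treated" if "treat" in preset.name else "control",
        body_weight_g=bw,
        lights_on_hour=preset.lights_on_hour,
    )
    rec.traces["flow"] = Trace("flow", flow, fs_flow, "mL/s")
    rec.traces["spo2"] = Trace("spo2", spo2, fs_spo2, "%")
    rec.annotations = {
        "hypoxia_onset_s": onset,
        "hvr_truth": {
            "ve_normoxia_ml_min_g": hp["ve_normoxia_ml_min_g"],
            "ve_hypoxia_ml_min_g": hp["ve_hypoxia_ml_min_g"],
            "spo2_normoxia": hp["spo2_normoxia"],
            "spo2_hypoxia": hp["spo2_hypoxia"],
            "hvr_ml_min_g_per_pct": abs(slope_norm),
        },
    }
    return rec
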