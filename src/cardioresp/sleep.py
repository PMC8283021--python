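"""Rule-based sleep staging and sleep-disordered-breathing scoring.

Stages are scored in 10-s epochs from EEG band content and EMG tone:
epochs with high delta-band (2–5 Hz) EEG power and sub-threshold EMG are
NREM; epochs with theta-dominant (5–10 Hz), low-amplitude EEG and muscle
atonia are REM; everything else is WAKE.  The EMG thresholds are
calibrated per recording from the percentile distribution of epoch EMG
RMS, which operationalizes a visual-scoring convention as a
deterministic rule.

Apneas are ≥90 % airflow reductions during sleep lasting at least two
local breath cycles or ≥0.7 s; the apnea index divides the apnea count
by total sleep time.  Oxygen desaturations are ≥5-point SpO2 drops from
a rolling baseline; the ODI divides their count by total sleep time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import welch

from .breaths import BreathTable, segment_breaths
from .core import Trace
from .signal_io import resample

__all__ = [
    "Hypnogram", "EventList", "SleepArchitecture", "StagingConfig",
    "score_epochs", "architecture", "select_analysis_windows",
    "detect_apneas", "apnea_index", "desaturation_events",
]

EPOCH_S = 10.0
APNEA_MIN_DURATION_S = 0.7
APNEA_AMP_FRAC = 0.10  # ≥90 % reduction
DESAT_DEPTH_PCT = 5.0


@dataclass
class Hypnogram:
    """Sequence of 10-s epoch stage labels."""

    stages: list[str]
    epoch_len_s: float = EPOCH_S
    start_clock_s: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.stages) - {"WAKE", "NREM", "REM"}
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return len(self.stages) * self.epoch_len_s

    def stage_at(self, t_s: float) -> str:
        i = int(t_s // self.epoch_len_s)
        return self.stages[min(max(i, 0), len(self.stages) - 1)]

    def is_sleep_at(self, t_s: float) -> bool:
        return self.stage_at(t_s) != "WAKE"


@dataclass
class EventList:
    """Scored apnea/desaturation events.

    Each event: ``type`` (APNEA or DESAT), ``start_s``, ``duration_s``
    and the stage at onset.
    """

    events: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def of_type(self, kind: str) -> list[dict]:
        return [e for e in self.events if e["type"] == kind]

    def count(self, kind: str, stage: str | None = None) -> int:
        return sum(1 for e in self.of_type(kind)
                   if stage is None or e["stage"] == stage)


@dataclass
class SleepArchitecture:
    """Summary of one polysomnogram: total sleep time and stage mix."""

    tst_min: float
    pct_nrem: float  # of total sleep time
    pct_rem: float
    efficiency_pct: float  # TST / recording duration
    n_epochs: int
    flagged: bool = False  # True when there was no sleep to summarize

    @property
    def tst_h(self) -> float:
        return self.tst_min / 60.0


@dataclass
class StagingConfig:
    """Thresholds of the epoch-staging rule.

    Band-ratio thresholds are absolute; the EMG thresholds are derived
    per recording from percentiles of the epoch EMG-RMS distribution:
    the WAKE threshold is the midpoint of (p50, p95), the atonia
    threshold the midpoint of (p05, p50).
    """

    delta_band: tuple[float, float] = (2.0, 5.0)
    theta_band: tuple[float, float] = (5.0, 10.0)
    delta_ratio: float = 1.5
    theta_ratio: float = 1.5
    emg_wake_pcts: tuple[float, float] = (50.0, 95.0)
    emg_atonia_pcts: tuple[float, float] = (5.0, 50.0)


def _band_power(f: np.ndarray, pxx: np.ndarray,
                band: tuple[float, float]) -> float:
    sel = (f >= band[0]) & (f < band[1])
    return float(np.trapezoid(pxx[sel], f[sel])) if sel.sum() > 1 else 0.0


def score_epochs(eeg: Trace, emg: Trace,
                 config: StagingConfig | None = None) -> Hypnogram:
    """Score 10-s epochs into WAKE / NREM / REM from EEG and EMG."""
    cfg = config or StagingConfig()
    if abs(eeg.duration_s - emg.duration_s) > 1e-6:
        raise ValueError("EEG and EMG must cover the same duration")
    if eeg.duration_s < EPOCH_S:
        raise ValueError("need at least one 10-s epoch")
    n_epochs = int(eeg.duration_s // EPOCH_S)
    spe_eeg = int(round(EPOCH_S * eeg.rate))
    spe_emg = int(round(EPOCH_S * emg.rate))
    delta = np.empty(n_epochs)
    theta = np.empty(n_epochs)
    emg_rms = np.empty(n_epochs)
    nper = min(spe_eeg, int(round(2.0 * eeg.rate)))
    for e in range(n_epochs):
        seg = eeg.values[e * spe_eeg:(e + 1) * spe_eeg]
        f, pxx = welch(seg - seg.mean(), fs=eeg.rate, nperseg=nper)
        delta[e] = _band_power(f, pxx, cfg.delta_band)
        theta[e] = _band_power(f, pxx, cfg.theta_band)
        mseg = emg.values[e * spe_emg:(e + 1) * spe_emg]
        emg_rms[e] = np.sqrt(np.mean(mseg ** 2))
    lo, hi = np.percentile(emg_rms, cfg.emg_wake_pcts)
    theta_m = (lo + hi) / 2.0
    lo, hi = np.percentile(emg_rms, cfg.emg_atonia_pcts)
    theta_atonia = min((lo + hi) / 2.0, theta_m)
    eps = 1e-30
    stages = []
    for e in range(n_epochs):
        d_ratio = delta[e] / (theta[e] + eps)
        t_ratio = theta[e] / (delta[e] + eps)
        if d_ratio > cfg.delta_ratio and emg_rms[e] < theta_m:
            stages.append("NREM")
        elif t_ratio > cfg.theta_ratio and emg_rms[e] < theta_atonia:
            stages.append("REM")
        else:
            stages.append("WAKE")
    return Hypnogram(stages=stages, start_clock_s=eeg.start_clock_s)


def architecture(hyp: Hypnogram,
                 recording_duration_s: float | None = None
                 ) -> SleepArchitecture:
    """Total sleep time, NREM/REM percentages and sleep efficiency."""
    n_nrem = sum(s == "NREM" for s in hyp.stages)
    n_rem = sum(s == "REM" for s in hyp.stages)
    n_sleep = n_nrem + n_rem
    duration = recording_duration_s or hyp.duration_s
    tst_min = n_sleep * hyp.epoch_len_s / 60.0
    if n_sleep == 0:
        return SleepArchitecture(0.0, float("nan"), float("nan"), 0.0,
                                 len(hyp), flagged=True)
    return SleepArchitecture(
        tst_min=tst_min,
        pct_nrem=100.0 * n_nrem / n_sleep,
        pct_rem=100.0 * n_rem / n_sleep,
        efficiency_pct=100.0 * tst_min * 60.0 / duration,
        n_epochs=len(hyp),
    )


def select_analysis_windows(hyp: Hypnogram, block_min: float = 30.0,
                            nrem_window_s: float = 20.0) -> list[dict]:
    """Ventilation-analysis windows: every REM run, plus one 20-s NREM
    window per 30-min block (the first run of ≥2 consecutive NREM
    epochs in the block).
    """
    windows: list[dict] = []
    el = hyp.epoch_len_s
    # REM runs
    i = 0
    while i < len(hyp):
        if hyp.stages[i] == "REM":
            j = i
            while j < len(hyp) and hyp.stages[j] == "REM":
                j += 1
            windows.append({"stage": "REM", "start_s": i * el,
                            "end_s": j * el})
            i = j
        else:
            i += 1
    # NREM subsamples
    epochs_per_block = int(block_min * 60.0 / el)
    need = max(2, int(np.ceil(nrem_window_s / el)))
    for b0 in range(0, len(hyp), epochs_per_block):
        block = hyp.stages[b0:b0 + epochs_per_block]
        for k in range(len(block) - need + 1):
            if all(s == "NREM" for s in block[k:k + need]):
                start = (b0 + k) * el
                windows.append({"stage": "NREM", "start_s": start,
                                "end_s": start + nrem_window_s})
                break
    return sorted(windows, key=lambda w: w["start_s"])


def detect_apneas(flow: Trace, hyp: Hypnogram,
                  breaths: BreathTable | None = None,
                  amp_frac: float = APNEA_AMP_FRAC,
                  min_duration_s: float = APNEA_MIN_DURATION_S,
                  n_baseline: int = 10) -> EventList:
    """Score apneas: breath amplitude ≤ ``amp_frac`` of the rolling
    baseline (median V_Imax of the preceding ``n_baseline`` breaths),
    lasting ≥ ``min_duration_s`` or at least two local breath cycles —
    either criterion suffices.  Events whose onset falls in a WAKE
    epoch are discarded.
    """
    if all(s == "WAKE" for s in hyp.stages):
        warnings.warn("no sleep epochs; apnea list is empty")
        return EventList()
    if breaths is None:
        breaths = segment_breaths(flow)
    if len(breaths) == 0:
        return EventList()
    onset = breaths["onset_s"].to_numpy()
    ttot = breaths["ttot_s"].to_numpy()
    ti = breaths["ti_s"].to_numpy()
    n = len(breaths)
    # amplitude for the reduction criterion: peak of the low-pass
    # envelope over the inspiration, so waveform noise riding on a
    # near-silent breath cannot lift it past the threshold (the raw
    # V_Imax stays untouched as a reported metric)
    smooth = uniform_filter1d(flow.values,
                              size=max(1, int(round(flow.rate / 20.0))))
    vmax = np.empty(n)
    for i in range(n):
        i0 = int(round(onset[i] * flow.rate))
        i1 = i0 + max(2, int(round(ti[i] * flow.rate)))
        vmax[i] = smooth[i0:i1].max()
    baseline = np.full(n, np.nan)
    cycle = np.full(n, np.nan)
    for i in range(n):
        j0 = max(0, i - n_baseline)
        if i - j0 >= 3:
            baseline[i] = np.median(vmax[j0:i])
            cycle[i] = np.median(ttot[j0:i])
    low = vmax <= amp_frac * baseline  # NaN baseline compares False

    events = []
    tol = 0.5 / flow.rate  # durations are quantized to sample indices

    def close_event(i0: int, i1: int) -> None:
        """Candidate run of low breaths [i0, i1]."""
        start = onset[i0]
        end = onset[i1] + ttot[i1]
        dur = end - start
        ref_cycle = cycle[i0]
        if np.isnan(ref_cycle):
            return
        if dur >= min_duration_s - tol or dur >= 2.0 * ref_cycle - tol:
            stage = hyp.stage_at(start)
            if stage != "WAKE":
                events.append({"type": "APNEA", "start_s": float(start),
                               "duration_s": float(dur), "stage": stage})

    i = 0
    while i < n:
        if low[i]:
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            close_event(i, j)
            i = j + 1
        else:
            i += 1

    # flow-silent gaps between delineated breaths (cycles rejected by the
    # physiological gate) also count when the amplitude criterion holds
    for i in range(n - 1):
        gap0 = onset[i] + ttot[i]
        gap = onset[i + 1] - gap0
        if gap < min_duration_s or np.isnan(baseline[i + 1]):
            continue
        i0 = int(gap0 * flow.rate)
        i1 = int(onset[i + 1] * flow.rate)
        seg = np.abs(flow.values[i0:i1])
        if seg.size and np.percentile(seg, 95) <= amp_frac * baseline[i + 1]:
            stage = hyp.stage_at(gap0)
            if stage != "WAKE":
                events.append({"type": "APNEA", "start_s": float(gap0),
                               "duration_s": float(gap), "stage": stage})
    events.sort(key=lambda e: e["start_s"])
    # enforce non-overlap within the type
    merged: list[dict] = []
    for ev in events:
        if merged and ev["start_s"] < (merged[-1]["start_s"]
                                       + merged[-1]["duration_s"]):
            continue
        merged.append(ev)
    return EventList(merged)


def apnea_index(events: EventList, arch: SleepArchitecture,
                stage: str | None = None) -> float:
    """Apneas per hour of total sleep time (optionally stage-stratified
    by the stage at event onset; the denominator stays TST).
    """
    if arch.tst_min <= 0:
        warnings.warn("zero total sleep time; apnea index undefined")
        return float("nan")
    return events.count("APNEA", stage) / arch.tst_h


def desaturation_events(spo2: Trace, hyp: Hypnogram,
                        depth_pct: float = DESAT_DEPTH_PCT,
                        recovery_pct: float = 2.0,
                        baseline_win_s: float = 60.0,
                        work_rate: float = 10.0
                        ) -> tuple[EventList, float, dict[str, float]]:
    """Score ≥``depth_pct``-point SpO2 drops from a rolling baseline.

    The baseline is the rolling median over the preceding
    ``baseline_win_s``; an event opens when SpO2 falls ``depth_pct``
    points below it (baseline frozen for the event) and closes on
    recovery to within ``recovery_pct`` points.  Returns the event
    list, the ODI (events per hour of total sleep time) and mean SpO2
    over NREM and REM epochs.  Detection runs on a ≤``work_rate`` Hz
    copy of the trace; desaturations evolve over tens of seconds.
    """
    if np.any(spo2.values <= 0) or np.any(spo2.values > 100):
        raise ValueError("SpO2 must lie in (0, 100] percent")
    x_tr = resample(spo2, min(spo2.rate, work_rate))
    x = x_tr.values
    rate = x_tr.rate
    win = max(1, int(round(baseline_win_s * rate)))
    base = (pd.Series(x).rolling(win, min_periods=1).median()
            .shift(1).bfill().to_numpy())
    events = []
    in_event = False
    frozen = start = 0.0
    stage = "WAKE"
    for i in range(x.size):
        t = i / rate
        if not in_event:
            if x[i] <= base[i] - depth_pct:
                in_event = True
                frozen = base[i]
                start = t
                stage = hyp.stage_at(t)
        elif x[i] >= frozen - recovery_pct:
            in_event = False
            if stage != "WAKE":
                events.append({"type": "DESAT", "start_s": float(start),
                               "duration_s": float(t - start),
                               "stage": stage})
    if in_event and stage != "WAKE":
        events.append({"type": "DESAT", "start_s": float(start),
                       "duration_s": float(x.size / rate - start),
                       "stage": stage})

    arch = architecture(hyp)
    odi = (len(events) / arch.tst_h if arch.tst_min > 0 else float("nan"))

    mean_by_stage: dict[str, float] = {}
    spe = int(round(hyp.epoch_len_s * spo2.rate))
    vals = {"NREM": [], "REM": []}
    for e, s in enumerate(hyp.stages):
        if s in vals and (e + 1) * spe <= spo2.n_samples:
            vals[s].append(spo2.values[e * spe:(e + 1) * spe])
    for s, chunks in vals.items():
        mean_by_stage[s] = (float(np.concatenate(chunks).mean())
                            if chunks else float("nan"))
    return EventList(events), odi, mean_by_stage
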