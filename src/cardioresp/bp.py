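"""Arterial-pressure telemetry summarization.

Reduces a continuous pressure waveform to per-beat systolic/diastolic
values, clock-aligned hourly means, MAP and heart rate, and light/dark
phase summaries suitable for group-level statistics.

MAP is computed from the hourly SBP/DBP means with the one-third
pulse-pressure rule, ``MAP = DBP + (SBP - DBP) / 3``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import Trace

__all__ = ["BeatSeries", "BPSummary", "detect_beats", "hourly_summary",
           "group_bp_table", "mean_arterial_pressure"]

MAX_HR_BPM = 800.0  # refractory limit for beat detection


def mean_arterial_pressure(sbp, dbp):
    """One-third pulse-pressure rule: ``DBP + (SBP - DBP)/3``."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    return dbp + (sbp - dbp) / 3.0


@dataclass
class BeatSeries:
    """Per-beat systolic/diastolic values at the beat (systolic peak) times."""

    beat_times: np.ndarray  # s from trace start
    sbp: np.ndarray  # mmHg
    dbp: np.ndarray  # mmHg
    start_clock_s: float = 0.0

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        if not (self.beat_times.size == self.sbp.size == self.dbp.size):
            raise ValueError("beat arrays must have equal length")
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.sbp < self.dbp):
            raise ValueError("systolic below diastolic in a beat")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size


@dataclass
class BPSummary:
    """Hourly and light/dark-phase blood-pressure summary for one animal."""

    hourly: pd.DataFrame  # columns: hour, clock_hour, phase, sbp, dbp, map, hr
    phase_means: pd.DataFrame  # index: phase; columns: sbp, dbp, map, hr
    animal_id: str = ""


def detect_beats(pressure: Trace, min_prominence_frac: float = 0.25,
                 flat_eps: float = 0.5) -> BeatSeries:
    """Per-cardiac-cycle SBP/DBP via peak/trough picking.

    Peaks must be separated by at least ``60 / 800`` s (no beats faster
    than 800 bpm) and be prominent relative to the waveform's pulse
    amplitude.  A flat trace yields an empty series with a warning.
    """
    if pressure.rate < 50:
        raise ValueError("beat detection needs >= 50 Hz sampling")
    x = pressure.values
    p2p = float(np.percentile(x, 98) - np.percentile(x, 2))
    if p2p < flat_eps:
        warnings.warn("pressure waveform has no pulsatile component; "
                      "returning empty beat series")
        return BeatSeries(np.array([]), np.array([]), np.array([]),
                          pressure.start_clock_s)
    distance = max(1, int(round(pressure.rate * 60.0 / MAX_HR_BPM)))
    # prominence search bounded to ~1 s: ample for any cardiac cycle and
    # keeps the scan linear on multi-hour recordings
    peaks, _ = find_peaks(x, distance=distance,
                          prominence=min_prominence_frac * p2p,
                          wlen=max(3, int(pressure.rate)))
    if peaks.size < 2:
        warnings.warn("fewer than two pressure peaks found")
        return BeatSeries(np.array([]), np.array([]), np.array([]),
                          pressure.start_clock_s)
    # diastolic: minimum between consecutive systolic peaks, assigned to
    # the later beat; the first beat reuses its following trough
    sbp = x[peaks].astype(float)
    dbp = np.empty_like(sbp)
    for i in range(1, peaks.size):
        dbp[i] = x[peaks[i - 1]:peaks[i]].min()
    dbp[0] = dbp[1] if peaks.size > 1 else sbp[0]
    dbp = np.minimum(dbp, sbp)
    return BeatSeries(peaks / pressure.rate, sbp, dbp,
                      pressure.start_clock_s)


def hourly_summary(beats: BeatSeries, lights_on_hour: float = 9.0,
                   animal_id: str = "") -> BPSummary:
    """Clock-aligned hourly SBP/DBP/MAP/HR plus light/dark phase means.

    Hours run from top of clock hour to top of the next; an hour with no
    beats is marked missing and excluded from the phase means.  The
    light phase is ``[lights_on, lights_on + 12 h)`` by clock time.
    """
    if beats.n_beats == 0:
        raise ValueError("no beats to summarize")
    clock = beats.start_clock_s + beats.beat_times  # s since midnight @ day 0
    if clock[-1] - clock[0] < 3600.0:
        raise ValueError("need at least one hour of beats")
    first_hour = np.floor(clock[0] / 3600.0)
    hour_idx = (np.floor(clock / 3600.0) - first_hour).astype(int)
    rows = []
    for h in range(hour_idx.max() + 1):
        sel = hour_idx == h
        clock_hour = (first_hour + h) % 24
        phase = ("light"
                 if (clock_hour - lights_on_hour) % 24 < 12 else "dark")
        if not np.any(sel):
            rows.append({"hour": h, "clock_hour": clock_hour, "phase": phase,
                         "sbp": np.nan, "dbp": np.nan, "map": np.nan,
                         "hr": np.nan, "n_beats": 0})
            continue
        # minutes of this clock hour actually covered by the recording
        h_start = (first_hour + h) * 3600.0
        covered_min = (min(h_start + 3600.0, clock[-1])
                       - max(h_start, clock[0])) / 60.0
        sbp = float(np.mean(beats.sbp[sel]))
        dbp = float(np.mean(beats.dbp[sel]))
        rows.append({
            "hour": h, "clock_hour": clock_hour, "phase": phase,
            "sbp": sbp, "dbp": dbp,
            "map": float(mean_arterial_pressure(sbp, dbp)),
            "hr": float(sel.sum() / max(covered_min, 1e-9)),
            "n_beats": int(sel.sum()),
        })
    hourly = pd.DataFrame(rows)
    valid = hourly[hourly["n_beats"] > 0]
    phase_means = (valid.groupby("phase")[["sbp", "dbp", "map", "hr"]]
                   .mean())
    return BPSummary(hourly=hourly, phase_means=phase_means,
                     animal_id=animal_id)


def group_bp_table(summaries: list[BPSummary]) -> tuple[pd.DataFrame,
                                                        pd.DataFrame]:
    """Tidy per-animal/phase table plus group mean ± SEM.

    Returns ``(per_animal, group)`` data frames.  ``per_animal`` has one
    row per animal and phase; ``group`` aggregates across animals with
    the standard error of the mean (SD/sqrt(n), ddof=1; 0 for n=1).
    """
    if not summaries:
        raise ValueError("no summaries to aggregate")
    rows = []
    for s in summaries:
        for phase, r in s.phase_means.iterrows():
            rows.append({"animal": s.animal_id, "phase": phase,
                         "map": r["map"], "sbp": r["sbp"],
                         "dbp": r["dbp"], "hr": r["hr"]})
    per_animal = pd.DataFrame(rows)

    def sem(x: pd.Series) -> float:
        return 0.0 if len(x) < 2 else float(x.std(ddof=1) / np.sqrt(len(x)))

    group = (per_animal.groupby("phase")[["map", "sbp", "dbp", "hr"]]
             .agg(["mean", sem, "count"]))
    group.columns = [f"{var}_{stat if stat != 'sem' else 'sem'}"
                     for var, stat in group.columns]
    return per_animal, group
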