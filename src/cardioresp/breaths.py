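"""Breath-by-breath analysis of calibrated plethysmography airflow.

Airflow is in mL/s with inspiration positive.  Breath onsets are
negative-to-positive zero crossings (with hysteresis against noise);
per breath the module measures inspiratory time Ti, cycle duration
Ttot, tidal volume V_T (integral of inspiratory flow), maximal
inspiratory airflow V_Imax, mean inspiratory flow rate MIFR = V_T/Ti
and inspiratory duty cycle DC = Ti/Ttot; respiratory rate RR = 60/Ttot
and instantaneous minute ventilation V_T × RR follow.  Inspiratory flow
limitation (IFL) — an early plateau of airflow while respiratory effort
keeps rising — is flagged per breath against configurable thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .core import Trace

__all__ = ["BreathTable", "IFLConfig", "segment_breaths",
           "minute_ventilation", "detect_ifl"]

TTOT_GATE_S = (0.1, 2.0)  # physiological cycle range, 30–600 breaths/min


@dataclass
class IFLConfig:
    """Quantitative reading of the flow-limitation definition.

    ``plateau_onset_frac``: flow must reach ``plateau_level_frac`` of
    V_Imax within this fraction of Ti; ``plateau_tol_frac``: allowed
    excursion around the plateau; ``plateau_min_frac``: minimum fraction
    of Ti spent on the plateau; ``effort_rise_frac``: required relative
    increase of effort over the plateau.
    """

    plateau_onset_frac: float = 0.40
    plateau_level_frac: float = 0.95
    plateau_tol_frac: float = 0.05
    plateau_min_frac: float = 0.40
    effort_rise_frac: float = 0.05


class BreathTable(pd.DataFrame):
    """Per-breath metrics; one row per breath.

    Columns: ``onset_s, ti_s, ttot_s, v_t_ml, v_imax_ml_s, mifr_ml_s,
    duty_cycle, rr_bpm, ve_ml_min, ifl``.
    """

    _metadata: list[str] = []

    @property
    def _constructor(self):
        return BreathTable

    @staticmethod
    def columns_order() -> list[str]:
        return ["onset_s", "ti_s", "ttot_s", "v_t_ml", "v_imax_ml_s",
                "mifr_ml_s", "duty_cycle", "rr_bpm", "ve_ml_min", "ifl"]


def _zero_crossings_up(x: np.ndarray, hyst: np.ndarray) -> np.ndarray:
    """Indices of negative-to-positive transitions with hysteresis.

    The signal must fall below ``-hyst`` before a crossing above
    ``+hyst`` counts, which suppresses noise-triggered micro-breaths.
    ``hyst`` may vary per sample (running-amplitude hysteresis).
    """
    state = np.where(x > hyst, 1, np.where(x < -hyst, -1, 0))
    nz = np.flatnonzero(state)
    if nz.size == 0:
        return np.array([], dtype=int)
    # forward-fill the nonzero states
    idx = np.maximum.accumulate(np.where(state != 0, np.arange(x.size), -1))
    filled = np.where(idx >= 0, state[np.clip(idx, 0, None)], 0)
    ups = np.flatnonzero((filled[1:] == 1) & (filled[:-1] == -1)) + 1
    return ups


def segment_breaths(flow: Trace, smooth_hz: float = 20.0,
                    hyst_frac: float = 0.02) -> BreathTable:
    """Delineate breaths and compute the per-breath metrics.

    Flow is low-pass smoothed (moving average of width ``1/smooth_hz``)
    before onset detection; metrics are measured on the raw trace.
    Cycles with Ttot outside 0.1–2 s are rejected as artifacts.
    """
    if flow.rate < 100:
        raise ValueError("breath segmentation needs >= 100 Hz airflow")
    x = flow.values
    width = max(1, int(round(flow.rate / smooth_hz)))
    xs = uniform_filter1d(x, size=width) if width > 1 else x
    amp = float(np.percentile(np.abs(xs), 95))
    if amp < 1e-9:
        return BreathTable(
            {c: pd.Series(dtype=float if c != "ifl" else object)
             for c in BreathTable.columns_order()})
    # running amplitude: local peak of |flow| over ~1.5 s, so the
    # hysteresis tracks down during apneas and the residual small
    # breaths still produce crossings; floored at 1 % of the global
    # amplitude to stay above pure noise in silent stretches
    local_amp = maximum_filter1d(np.abs(xs),
                                 size=int(round(1.5 * flow.rate)))
    hyst = hyst_frac * np.maximum(local_amp, 0.01 * amp)
    onsets = _zero_crossings_up(xs, hyst)
    # the centred smoothing offsets the detected crossing from the raw
    # zero crossing (late into the inspiration after a large expiration,
    # early into the expiratory tail after a shallow one); snap each
    # onset to the raw negative-to-positive transition
    refined = []
    for a in onsets:
        if x[a] > 0:
            while a > 0 and x[a - 1] > 0:
                a -= 1
        else:
            while a < x.size - 1 and x[a] <= 0:
                a += 1
        if not refined or a > refined[-1]:
            refined.append(a)
    onsets = np.asarray(refined, dtype=int)
    rows = []
    dt = 1.0 / flow.rate
    for a, b in zip(onsets[:-1], onsets[1:]):
        ttot = (b - a) * dt
        if not TTOT_GATE_S[0] <= ttot <= TTOT_GATE_S[1]:
            continue
        seg = x[a:b]
        pos = seg > 0
        if not np.any(pos):
            continue
        # inspiratory lobe: the run of positive flow containing the
        # cycle's maximum (noise blips near the zero crossing form tiny
        # positive runs that must not be mistaken for the inspiration)
        i_peak = int(np.argmax(seg))
        if not pos[i_peak]:
            continue
        i_start = i_peak
        while i_start > 0 and pos[i_start - 1]:
            i_start -= 1
        i_end = i_peak
        while i_end < seg.size and pos[i_end]:
            i_end += 1
        if i_end - i_start < 2:
            continue
        ti = (i_end - i_start) * dt
        # integrate with the zero-clipped boundary samples included so
        # the rising/falling edges are not truncated mid-sample
        lo = max(0, i_start - 1)
        insp = np.clip(seg[lo:min(seg.size, i_end + 1)], 0.0, None)
        v_t = float(np.trapezoid(insp, dx=dt))
        if v_t <= 0:
            continue
        v_imax = float(insp.max())
        rows.append({
            "onset_s": a * dt, "ti_s": ti, "ttot_s": ttot,
            "v_t_ml": v_t, "v_imax_ml_s": v_imax,
            "mifr_ml_s": v_t / ti, "duty_cycle": ti / ttot,
            "rr_bpm": 60.0 / ttot, "ve_ml_min": v_t * 60.0 / ttot,
            "ifl": None,
        })
    if not rows:
        return BreathTable(
            {c: pd.Series(dtype=float if c != "ifl" else object)
             for c in BreathTable.columns_order()})
    return BreathTable(pd.DataFrame(rows, columns=BreathTable.columns_order()))


def minute_ventilation(breaths: BreathTable,
                       body_weight_g: float) -> tuple[float, float]:
    """Mean minute ventilation (mL/min) and its body-weight-normalized
    value (mL/min/g): ``V_E = mean(V_T * 60 / Ttot)``.
    """
    if len(breaths) == 0:
        raise ValueError("no breaths to average")
    if not body_weight_g > 0:
        raise ValueError("body weight must be positive")
    ve = float((breaths["v_t_ml"] * 60.0 / breaths["ttot_s"]).mean())
    return ve, ve / body_weight_g


def detect_ifl(breaths: BreathTable, flow: Trace,
               effort: Trace | None = None,
               config: IFLConfig | None = None) -> BreathTable:
    """Flag inspiratory flow limitation per breath.

    A breath is IFL when (a) flow reaches ``plateau_level_frac`` of
    V_Imax within the first ``plateau_onset_frac`` of Ti, (b) stays
    within ``plateau_tol_frac`` of that plateau for at least
    ``plateau_min_frac`` of Ti, and (c) effort amplitude rises over the
    plateau (second-half mean exceeds first-half mean by
    ``effort_rise_frac``).  Without an effort channel the flags stay
    null and a warning is raised.
    """
    cfg = config or IFLConfig()
    out = breaths.copy()
    if effort is None:
        warnings.warn("no effort channel; IFL flags left null")
        out["ifl"] = None
        return out
    flags = []
    for _, br in out.iterrows():
        i0 = int(round(br["onset_s"] * flow.rate))
        n_i = max(2, int(round(br["ti_s"] * flow.rate)))
        seg = flow.values[i0:i0 + n_i]
        v_imax = float(seg.max())
        if v_imax <= 0:
            flags.append(False)
            continue
        level = cfg.plateau_level_frac * v_imax
        above = np.flatnonzero(seg >= level)
        if above.size == 0 or above[0] > cfg.plateau_onset_frac * n_i:
            flags.append(False)  # (a) no early plateau
            continue
        near = np.abs(seg - v_imax) <= cfg.plateau_tol_frac * v_imax
        if near.sum() < cfg.plateau_min_frac * n_i:
            flags.append(False)  # (b) plateau too short
            continue
        plateau_idx = np.flatnonzero(near)
        j0 = int(round(br["onset_s"] * effort.rate))
        m = max(2, int(round(br["ti_s"] * effort.rate)))
        eseg = np.abs(effort.values[j0:j0 + m])
        lo = int(plateau_idx[0] / flow.rate * effort.rate)
        hi = int(plateau_idx[-1] / flow.rate * effort.rate) + 1
        eseg = eseg[lo:hi]
        if eseg.size < 4:
            flags.append(False)
            continue
        half = eseg.size // 2
        first, second = eseg[:half].mean(), eseg[half:].mean()
        flags.append(bool(first > 0
                          and second >= (1 + cfg.effort_rise_frac) * first))
    out["ifl"] = flags
    return out
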