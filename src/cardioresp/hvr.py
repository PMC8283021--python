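"""Hypoxic ventilatory response (HVR) from a normoxia→hypoxia challenge.

The HVR is the slope of minute ventilation against oxygen saturation
across the normoxic baseline and the acute hypoxic response, normalized
to body weight and reported positive.  Ventilation comes from
breath-by-breath analysis of the airflow channel; each breath is paired
with the concurrent SpO2 sample and the slope is an ordinary
least-squares fit over the pooled breaths of both analysis windows.

Windows follow the challenge protocol: the hypoxic window covers
[onset + 30 s, onset + 120 s) — the first 30 s of gas exchange are
excluded and the peripheral-chemoreflex-dominated response up to 2 min
is kept; the normoxic reference is the final 5 min before the switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .breaths import BreathTable, segment_breaths
from .core import Recording

__all__ = ["HVRResult", "split_challenge", "compute_hvr"]

NORMOXIC_WINDOW_S = 300.0  # final 5 min of the normoxic period
HYPOXIC_SKIP_S = 30.0
HYPOXIC_END_S = 120.0


@dataclass
class HVRResult:
    """Ventilatory response of one challenge cycle.

    ``slope_raw`` is the OLS slope of V_E (mL/min) on SpO2 (%);
    ``hvr`` = |slope| / body weight, in mL/min/g per % SpO2.
    """

    ve_normoxia: float  # mL/min/g
    ve_hypoxia: float  # mL/min/g
    spo2_normoxia: float  # %
    spo2_hypoxia: float  # %
    slope_raw: float  # mL/min per % SpO2
    hvr: float  # mL/min/g per % SpO2
    n_breaths: int


def split_challenge(rec: Recording, hypoxia_onset_s: float
                    ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Analysis windows ``(normoxic, hypoxic)`` as (start, end) seconds.

    Normoxic: the 5 min immediately before the gas switch; hypoxic:
    [onset + 30 s, onset + 120 s).  Raises when the recording does not
    cover both windows.
    """
    flow = rec["flow"]
    t0 = hypoxia_onset_s - NORMOXIC_WINDOW_S
    t1 = hypoxia_onset_s + HYPOXIC_END_S
    if t0 < 0 or t1 > flow.duration_s + 1e-9:
        raise ValueError(
            f"recording ({flow.duration_s:.0f} s) does not cover "
            f"[{t0:.0f}, {t1:.0f}) s around the hypoxia onset"
        )
    normoxic = (t0, hypoxia_onset_s)
    hypoxic = (hypoxia_onset_s + HYPOXIC_SKIP_S,
               hypoxia_onset_s + HYPOXIC_END_S)
    return normoxic, hypoxic


def _window_breaths(breaths: BreathTable,
                    window: tuple[float, float]) -> BreathTable:
    t0, t1 = window
    sel = (breaths["onset_s"] >= t0) & (breaths["onset_s"] < t1)
    return breaths[sel]


def compute_hvr(rec: Recording,
                windows: tuple[tuple[float, float],
                               tuple[float, float]] | None = None,
                hypoxia_onset_s: float | None = None,
                breaths: BreathTable | None = None,
                mean_regression: bool = False) -> HVRResult:
    """Ventilatory response slope over the pooled challenge windows.

    Per-breath minute ventilation (V_T × 60/Ttot, mL/min) is paired
    with the nearest SpO2 sample at the breath onset; the OLS slope of
    V_E on SpO2 over both windows gives ``slope_raw`` and
    ``hvr = -slope/BW`` (positive when ventilation rises as saturation
    falls).  With ``mean_regression`` the fit uses the two window means
    only, which for two equally weighted clusters gives the same slope.
    """
    if windows is None:
        if hypoxia_onset_s is None:
            raise ValueError("provide windows or hypoxia_onset_s")
        windows = split_challenge(rec, hypoxia_onset_s)
    norm_w, hyp_w = windows
    if "flow" not in rec or "spo2" not in rec:
        raise ValueError("recording needs flow and spo2 traces")
    if breaths is None:
        breaths = segment_breaths(rec["flow"])
    spo2 = rec["spo2"]
    bw = rec.body_weight_g

    ve_parts, sp_parts, means = [], [], {}
    for name, win in (("normoxia", norm_w), ("hypoxia", hyp_w)):
        sub = _window_breaths(breaths, win)
        if len(sub) == 0:
            raise ValueError(f"no breaths inside the {name} window")
        ve = (sub["v_t_ml"] * 60.0 / sub["ttot_s"]).to_numpy()
        idx = np.clip(np.round(sub["onset_s"].to_numpy() * spo2.rate
                               ).astype(int), 0, spo2.n_samples - 1)
        sp = spo2.values[idx]
        means[name] = (float(ve.mean()), float(sp.mean()))
        ve_parts.append(ve)
        sp_parts.append(sp)

    if mean_regression:
        x = np.array([means["normoxia"][1], means["hypoxia"][1]])
        y = np.array([means["normoxia"][0], means["hypoxia"][0]])
    else:
        x = np.concatenate(sp_parts)
        y = np.concatenate(ve_parts)
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate regression: SpO2 has zero variance")
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    return HVRResult(
        ve_normoxia=means["normoxia"][0] / bw,
        ve_hypoxia=means["hypoxia"][0] / bw,
        spo2_normoxia=means["normoxia"][1],
        spo2_hypoxia=means["hypoxia"][1],
        slope_raw=slope,
        hvr=abs(slope) / bw,
        n_breaths=int(sum(v.size for v in ve_parts)),
    )
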