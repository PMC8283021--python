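"""Heart-rate-variability spectral analysis of an instantaneous-HR channel.

The procedure: physiologically impossible readings (< 200 or > 800 bpm)
are masked and filled by linear interpolation; the reciprocal of heart
rate gives the beat-to-beat interval series; the series is windowed into
2-min segments overlapping by 1 min, mean-removed and Hamming-tapered;
each segment's one-sided periodogram is aggregated into 0.1 Hz bins; low
frequency (LF) power sums the 0.4–1.5 Hz bins and high frequency (HF)
the 1.6–4.0 Hz bins, with band membership decided by the bin's grid
label (its lower edge), so the 1.5–1.6 Hz bin belongs to LF.  Segment LF
and HF are averaged across segments and the LF/HF ratio is the ratio of
those averages.

The native resolution of a 2-min window is 1/120 Hz; the 0.1 Hz bins
aggregate exactly 12 raw bins each, conserving total power (Parseval,
window-compensated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import periodogram

from .core import Trace
from .signal_io import resample

__all__ = [
    "SpectralSummary", "filter_hr_artifacts", "to_beat_interval",
    "segment_windows", "psd_binned", "band_powers", "hrv_summary",
    "HR_MIN_BPM", "HR_MAX_BPM", "LF_BAND", "HF_BAND",
]

HR_MIN_BPM = 200.0
HR_MAX_BPM = 800.0
BIN_WIDTH_HZ = 0.1
LF_BAND = (0.4, 1.5)  # inclusive bin labels, Hz
HF_BAND = (1.6, 4.0)


@dataclass
class SpectralSummary:
    """Averaged band powers of the beat-interval series.

    Powers are in s²; multiply by 1e6 for ms².  ``lf_hf_ratio`` is None
    when the HF power is zero (flagged rather than infinite).
    """

    lf: float
    hf: float
    lf_hf_ratio: Optional[float]
    n_segments: int
    bin_freqs: np.ndarray  # bin labels (lower edges), Hz
    mean_psd: np.ndarray  # binned power per 0.1 Hz bin, s²

    @property
    def lf_ms2(self) -> float:
        return self.lf * 1e6

    @property
    def hf_ms2(self) -> float:
        return self.hf * 1e6


def filter_hr_artifacts(hr: Trace, lo: float = HR_MIN_BPM,
                        hi: float = HR_MAX_BPM) -> Trace:
    """Mask readings strictly below ``lo`` or above ``hi`` bpm and fill
    them by linear interpolation between the nearest valid neighbours.

    Leading/trailing invalid runs take the nearest valid value.  Border
    values (exactly 200 or 800 bpm) are retained.
    """
    x = hr.values
    valid = (x >= lo) & (x <= hi)
    if hr.valid is not None:
        valid &= hr.valid
    if not np.any(valid):
        raise ValueError("no valid heart-rate samples")
    idx = np.arange(x.size)
    filled = np.interp(idx, idx[valid], x[valid])
    return Trace(hr.label, filled, hr.rate, hr.units, hr.start_clock_s)


def to_beat_interval(hr: Trace) -> Trace:
    """Beat-to-beat interval estimate: ``interval_s = 60 / hr_bpm``."""
    if np.any(hr.values <= 0):
        raise ValueError(
            "non-positive heart-rate sample; run filter_hr_artifacts first"
        )
    return Trace("beat_interval", 60.0 / hr.values, hr.rate, "s",
                 hr.start_clock_s)


def segment_windows(x: Trace, win_s: float = 120.0,
                    step_s: float = 60.0) -> list[np.ndarray]:
    """Mean-removed, Hamming-tapered overlapping segments.

    A trace of duration T yields ``floor((T - win)/step) + 1`` segments.
    """
    n_win = int(round(win_s * x.rate))
    n_step = int(round(step_s * x.rate))
    if x.n_samples < n_win:
        raise ValueError(
            f"trace shorter ({x.duration_s:.0f} s) than window ({win_s} s)"
        )
    window = np.hamming(n_win)
    out = []
    for start in range(0, x.n_samples - n_win + 1, n_step):
        seg = x.values[start:start + n_win]
        out.append((seg - seg.mean()) * window)
    return out


def psd_binned(segment: np.ndarray, fs: float,
               bin_width: float = BIN_WIDTH_HZ) -> tuple[np.ndarray,
                                                         np.ndarray]:
    """One-sided periodogram of a pre-windowed segment, aggregated into
    contiguous ``bin_width`` bins.

    Returns ``(bin_labels, bin_power)`` where each label is the bin's
    lower edge on the 0.1 Hz grid and the power (signal units², e.g. s²)
    is the sum of raw-bin power density × raw resolution, compensated
    for the Hamming window's power (mean of w²).  Total binned power
    equals total raw power by construction.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.size
    window = np.hamming(n)
    # segment arrives already tapered; periodogram with a boxcar window
    # and manual window-power compensation keeps the scaling explicit
    f, pxx = periodogram(segment, fs=fs, window="boxcar",
                         detrend=False, scaling="density")
    pxx = pxx / np.mean(window ** 2)
    df = fs / n
    raw_power = pxx * df  # units² per raw bin
    labels = np.floor(f / bin_width + 1e-9)
    n_bins = int(labels.max()) + 1
    power = np.bincount(labels.astype(int), weights=raw_power,
                        minlength=n_bins)
    freqs = np.arange(n_bins) * bin_width
    return freqs, power


@dataclass
class _SegmentBands:
    lf: float
    hf: float


def _band_sum(freqs: np.ndarray, power: np.ndarray,
              band: tuple[float, float]) -> float:
    lo, hi = band
    sel = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return float(power[sel].sum())


def band_powers(psd_list: list[tuple[np.ndarray, np.ndarray]]
                ) -> SpectralSummary:
    """Average LF/HF across segment PSDs; ratio of the averages.

    LF sums bins labelled 0.4–1.5 Hz, HF bins labelled 1.6–4.0 Hz (both
    inclusive).  When the averaged HF power is zero the ratio is flagged
    as None.
    """
    if not psd_list:
        raise ValueError("need at least one segment PSD")
    lf_vals, hf_vals = [], []
    freqs0 = psd_list[0][0]
    acc = np.zeros_like(psd_list[0][1])
    for freqs, power in psd_list:
        lf_vals.append(_band_sum(freqs, power, LF_BAND))
        hf_vals.append(_band_sum(freqs, power, HF_BAND))
        m = min(acc.size, power.size)
        acc[:m] += power[:m]
    lf = float(np.mean(lf_vals))
    hf = float(np.mean(hf_vals))
    ratio = lf / hf if hf > 0 else None
    return SpectralSummary(lf=lf, hf=hf, lf_hf_ratio=ratio,
                           n_segments=len(psd_list), bin_freqs=freqs0,
                           mean_psd=acc / len(psd_list))


def hrv_summary(hr: Trace, analysis_rate: float = 20.0,
                win_s: float = 120.0, step_s: float = 60.0
                ) -> SpectralSummary:
    """Full pipeline: artifact filter → interval series → windowed
    segments → binned PSDs → band powers.

    The interval series is analysed as a uniformly sampled signal,
    downsampled to ``analysis_rate`` (Nyquist 10 Hz comfortably above
    the 4 Hz band ceiling).
    """
    clean = filter_hr_artifacts(hr)
    ibi = to_beat_interval(clean)
    if abs(ibi.rate - analysis_rate) > 1e-12 and ibi.rate > analysis_rate:
        ibi = resample(ibi, analysis_rate)
    segs = segment_windows(ibi, win_s=win_s, step_s=step_s)
    psds = [psd_binned(s, ibi.rate) for s in segs]
    return band_powers(psds)
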