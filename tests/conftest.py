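"""Shared fixtures: presets and one scored polysomnography session.

Synthetic sessions are generated at reduced sampling rates (EEG/EMG
100 Hz, airflow 400 Hz, SpO2 25 Hz) — ample for 2–10 Hz EEG bands and
sub-second breaths — to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cardioresp import bp, breaths, sleep, synth

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def baseline_preset() -> synth.SynthPreset:
    return synth.load_preset("nzo-baseline")


@pytest.fixture(scope="session")
def psg(baseline_preset) -> "synth.Recording":
    """One 6-h baseline polysomnography session with ground truth."""
    return synth.gen_sleep_session(baseline_preset, fs_eeg=100.0,
                                   fs_flow=400.0, fs_spo2=25.0)


@pytest.fixture(scope="session")
def psg_scored(psg):
    """Scored hypnogram, breath table, architecture and apnea events."""
    hyp = sleep.score_epochs(psg["eeg"], psg["emg"])
    table = breaths.segment_breaths(psg["flow"])
    arch = sleep.architecture(hyp)
    apneas = sleep.detect_apneas(psg["flow"], hyp, breaths=table)
    return {"hyp": hyp, "breaths": table, "arch": arch, "apneas": apneas}


@pytest.fixture(scope="session")
def hvr_session(baseline_preset):
    """Synthetic normoxia→hypoxia challenge, body weight 42 g."""
    return synth.gen_hvr_session(baseline_preset, body_weight_g=42.0,
                                 fs_flow=400.0)


def run_bp_cohort(preset: synth.SynthPreset, n_animals: int, fs: float):
    """Full telemetry pipeline on a synthetic cohort; returns the group
    table from :func:`cardioresp.bp.group_bp_table`."""
    summaries = []
    for rec in synth.gen_bp_telemetry(preset, n_animals, fs=fs):
        beats = bp.detect_beats(rec["pressure"])
        summaries.append(bp.hourly_summary(beats, rec.lights_on_hour,
                                           rec.animal_id))
    return bp.group_bp_table(summaries)


def make_flow_with_breaths(ttots: list[tuple[float, float]], fs: float = 1000.0,
                           duty: float = 0.5, amp: float = 2.0) -> np.ndarray:
    """Concatenate half-sine breaths; each entry is (Ttot s, scale)."""
    parts = []
    for ttot, scale in ttots:
        n_i = int(round(duty * ttot * fs))
        n_e = int(round(ttot * fs)) - n_i
        insp = amp * scale * np.sin(np.pi * np.arange(n_i) / n_i)
        expv = -amp * scale * np.sin(np.pi * np.arange(n_e) / n_e)
        parts.extend([insp, expv])
    return np.concatenate(parts)
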