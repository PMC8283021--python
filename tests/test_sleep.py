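"""Sleep staging, architecture, analysis windows and SDB event scoring."""

import numpy as np
import pytest
from scipy.stats import poisson

from cardioresp import sleep
from cardioresp.core import Trace
from conftest import make_flow_with_breaths


def build_psg_epochs(spec, fs=100.0):
    """EEG/EMG traces from per-epoch (eeg_freq, eeg_amp, emg_rms)."""
    rng = np.random.default_rng(0)
    eeg, emg = [], []
    n = int(10.0 * fs)
    t = np.arange(n) / fs
    for freq, amp, tone in spec:
        eeg.append(amp * np.sin(2 * np.pi * freq * t))
        emg.append(tone * rng.standard_normal(n))
    return (Trace("eeg", np.concatenate(eeg), fs, "uV"),
            Trace("emg", np.concatenate(emg), fs, "uV"))


WAKEY = (8.0, 50.0, 60.0)
NREMY = (3.0, 300.0, 20.0)
REMY = (7.0, 100.0, 2.0)


class TestScoreEpochs:
    def test_stage_rules(self):
        eeg, emg = build_psg_epochs([WAKEY] * 4 + [NREMY] * 5 + [REMY] * 2)
        hyp = sleep.score_epochs(eeg, emg)
        assert hyp.stages == (["WAKE"] * 4 + ["NREM"] * 5 + ["REM"] * 2)

    def test_high_emg_forces_wake_despite_nrem_eeg(self):
        spec = [WAKEY] * 4 + [NREMY] * 5 + [REMY] * 2 + [(3.0, 300.0, 80.0)]
        eeg, emg = build_psg_epochs(spec)
        hyp = sleep.score_epochs(eeg, emg)
        assert hyp.stages[-1] == "WAKE"

    def test_unequal_durations_rejected(self):
        eeg, _ = build_psg_epochs([NREMY] * 3)
        _, emg = build_psg_epochs([NREMY] * 2)
        with pytest.raises(ValueError, match="duration"):
            sleep.score_epochs(eeg, emg)

    def test_recovery_on_synthetic_session(self, psg, psg_scored):
        """Scored hypnogram agrees with ground truth on ≥90 % of epochs
        for clean synthetic signals."""
        truth = psg.annotations["hypnogram"]
        scored = psg_scored["hyp"].stages
        agree = np.mean([a == b for a, b in zip(scored, truth)])
        assert agree >= 0.90


class TestArchitecture:
    def test_arithmetic(self):
        hyp = sleep.Hypnogram(["NREM"] * 1080 + ["REM"] * 120
                              + ["WAKE"] * 960)
        arch = sleep.architecture(hyp)
        assert arch.tst_min == pytest.approx(200.0)
        assert arch.pct_nrem == pytest.approx(90.0)
        assert arch.pct_rem == pytest.approx(10.0)
        assert arch.efficiency_pct == pytest.approx(55.6, abs=0.1)

    def test_all_wake_is_flagged(self):
        arch = sleep.architecture(sleep.Hypnogram(["WAKE"] * 100))
        assert arch.flagged and arch.tst_min == 0.0
        assert np.isnan(arch.pct_nrem)

    def test_all_nrem(self):
        arch = sleep.architecture(sleep.Hypnogram(["NREM"] * 100))
        assert arch.efficiency_pct == pytest.approx(100.0)
        assert arch.pct_nrem == pytest.approx(100.0)


class TestAnalysisWindows:
    def test_at_most_one_nrem_window_per_block(self):
        rng = np.random.default_rng(1)
        stages = list(rng.choice(["WAKE", "NREM", "REM"], size=2160))
        windows = sleep.select_analysis_windows(sleep.Hypnogram(stages))
        nrem = [w for w in windows if w["stage"] == "NREM"]
        assert len(nrem) <= 12  # 6 h / 30 min

    def test_rem_windows_cover_all_rem_epochs(self):
        stages = (["WAKE"] * 10 + ["REM"] * 66 + ["NREM"] * 10
                  + ["REM"] * 66)  # 22 min of REM in total
        windows = sleep.select_analysis_windows(sleep.Hypnogram(stages))
        rem_total = sum(w["end_s"] - w["start_s"] for w in windows
                        if w["stage"] == "REM")
        assert rem_total == pytest.approx(22 * 60.0)

    def test_block_without_nrem_yields_no_window(self):
        stages = ["WAKE"] * 180 + ["NREM"] * 180
        windows = sleep.select_analysis_windows(sleep.Hypnogram(stages))
        nrem = [w for w in windows if w["stage"] == "NREM"]
        assert len(nrem) == 1
        assert nrem[0]["start_s"] >= 1800.0


def apnea_test_flow(event_breaths, fs=1000.0, baseline_ttot=0.6):
    """15 normal breaths, the given (ttot, scale) events, 15 more."""
    spec = ([(baseline_ttot, 1.0)] * 15 + event_breaths
            + [(baseline_ttot, 1.0)] * 15)
    x = make_flow_with_breaths(spec, fs=fs)
    return Trace("flow", x, fs, "mL/s")


ALL_NREM = sleep.Hypnogram(["NREM"] * 6)


class TestApneaRule:
    def test_point7s_event_is_scored(self):
        """95 % reduction lasting 0.7 s (local cycle 0.6 s) → one apnea."""
        flow = apnea_test_flow([(0.7, 0.05)])
        events = sleep.detect_apneas(flow, ALL_NREM)
        assert events.count("APNEA") == 1
        assert events.events[0]["duration_s"] == pytest.approx(0.7,
                                                               abs=0.02)

    def test_shorter_event_is_not_scored(self):
        """0.65 s < 0.7 s and < two 0.6 s cycles → no apnea."""
        flow = apnea_test_flow([(0.65, 0.05)])
        assert sleep.detect_apneas(flow, ALL_NREM).count("APNEA") == 0

    def test_two_cycle_criterion_alone_suffices(self):
        """1.3 s ≥ 2 × 0.6 s cycles scores even with the absolute-duration
        rule disabled."""
        flow = apnea_test_flow([(0.65, 0.05), (0.65, 0.05)])
        events = sleep.detect_apneas(flow, ALL_NREM,
                                     min_duration_s=np.inf)
        assert events.count("APNEA") == 1

    def test_mild_reduction_is_not_apnea(self):
        """An 80 % reduction misses the ≥90 % criterion."""
        flow = apnea_test_flow([(0.7, 0.20)])
        assert sleep.detect_apneas(flow, ALL_NREM).count("APNEA") == 0

    def test_wake_events_are_discarded(self):
        flow = apnea_test_flow([(0.7, 0.05)])
        all_wake = sleep.Hypnogram(["WAKE"] * 6)
        with pytest.warns(UserWarning, match="no sleep"):
            events = sleep.detect_apneas(flow, all_wake)
        assert len(events) == 0

    def test_threshold_monotonicity(self, psg, psg_scored):
        """Raising the amplitude threshold from 10 % to 20 % never
        decreases the apnea count."""
        n10 = len(sleep.detect_apneas(psg["flow"], psg_scored["hyp"],
                                      breaths=psg_scored["breaths"],
                                      amp_frac=0.10))
        n20 = len(sleep.detect_apneas(psg["flow"], psg_scored["hyp"],
                                      breaths=psg_scored["breaths"],
                                      amp_frac=0.20))
        assert n20 >= n10


class TestApneaIndex:
    def test_arithmetic(self):
        events = sleep.EventList([{"type": "APNEA", "start_s": float(i),
                                   "duration_s": 0.8, "stage": "REM"}
                                  for i in range(102)])
        arch = sleep.SleepArchitecture(195.1, 90.0, 10.0, 60.0, 2160)
        assert sleep.apnea_index(events, arch) == pytest.approx(31.4,
                                                                abs=0.05)

    def test_zero_events(self):
        arch = sleep.SleepArchitecture(100.0, 90.0, 10.0, 60.0, 2160)
        assert sleep.apnea_index(sleep.EventList(), arch) == 0.0

    def test_zero_tst_flagged(self):
        arch = sleep.SleepArchitecture(0.0, np.nan, np.nan, 0.0, 100,
                                       flagged=True)
        with pytest.warns(UserWarning):
            assert np.isnan(sleep.apnea_index(sleep.EventList(), arch))

    def test_recovered_count_within_poisson_interval(self, psg,
                                                     psg_scored):
        """Scored apnea count falls in the 95 % Poisson interval of the
        inserted event count."""
        inserted = sum(e["type"] == "APNEA"
                       for e in psg.annotations["events"])
        scored = psg_scored["apneas"].count("APNEA")
        lo, hi = poisson.ppf([0.025, 0.975], inserted)
        assert lo <= scored <= hi


class TestDesaturations:
    def _spo2(self, dips, fs=5.0, duration_s=600.0):
        x = np.full(int(duration_s * fs), 97.0)
        for start, dur, depth in dips:
            i0, i1 = int(start * fs), int((start + dur) * fs)
            x[i0:i1] -= depth
        return Trace("spo2", x, fs, "%")

    def test_six_point_dip_scores_one_event(self):
        hyp = sleep.Hypnogram(["NREM"] * 60)
        ev, odi, _ = sleep.desaturation_events(
            self._spo2([(200.0, 30.0, 6.0)]), hyp)
        assert len(ev) == 1
        assert ev.events[0]["stage"] == "NREM"

    def test_sub_threshold_dip_ignored(self):
        hyp = sleep.Hypnogram(["NREM"] * 60)
        ev, odi, _ = sleep.desaturation_events(
            self._spo2([(200.0, 30.0, 4.5)]), hyp)
        assert len(ev) == 0 and odi == 0.0

    def test_constant_spo2(self):
        hyp = sleep.Hypnogram(["NREM"] * 30 + ["REM"] * 30)
        ev, odi, mean_spo2 = sleep.desaturation_events(
            self._spo2([]), hyp)
        assert odi == 0.0
        assert mean_spo2["NREM"] == pytest.approx(97.0)
        assert mean_spo2["REM"] == pytest.approx(97.0)

    def test_wake_dips_do_not_count(self):
        hyp = sleep.Hypnogram(["WAKE"] * 30 + ["NREM"] * 30)
        ev, odi, _ = sleep.desaturation_events(
            self._spo2([(100.0, 30.0, 6.0)]), hyp)
        assert len(ev) == 0

    def test_out_of_range_rejected(self):
        hyp = sleep.Hypnogram(["NREM"] * 6)
        bad = Trace("spo2", np.full(300, 102.0), 5.0, "%")
        with pytest.raises(ValueError, match="SpO2"):
            sleep.desaturation_events(bad, hyp)

    def test_every_inserted_desat_is_scored(self, psg, psg_scored):
        """All generator-inserted ≥5-point desaturations during sleep
        appear in the scored list."""
        ev, odi, _ = sleep.desaturation_events(psg["spo2"],
                                               psg_scored["hyp"])
        truth = [e for e in psg.annotations["events"]
                 if e["type"] == "DESAT"]
        for t in truth:
            hit = any(abs(e["start_s"] - t["start_s"]) < 15.0
                      for e in ev.events)
            assert hit, f"desaturation at {t['start_s']:.0f} s missed"
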