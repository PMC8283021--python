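"""Generator-level tests: determinism, ground-truth consistency and
spectral energy placement of the synthetic signals."""

import numpy as np
import pytest

from cardioresp import synth


class TestPresets:
    def test_library_loads(self):
        names = synth.available_presets()
        assert "nzo-baseline" in names and "alloaca-treated" in names
        p = synth.load_preset("nzo-baseline")
        # preset encodes the group MAP values via the one-third rule
        sbp, dbp = p.bp_light_mean
        assert dbp + (sbp - dbp) / 3 == pytest.approx(134.9)
        t = synth.load_preset("alloaca-treated")
        sbp, dbp = t.bp_light_mean
        assert dbp + (sbp - dbp) / 3 == pytest.approx(124.9)

    def test_stage_fractions_sum_to_one(self, baseline_preset):
        assert sum(baseline_preset.stage_fractions().values()) == (
            pytest.approx(1.0))

    @pytest.mark.parametrize("bad", [
        {"duration_h": 0.0},
        {"apnea_rate": -1.0},
        {"desat_depth": -2.0},
        {"body_weight_g": 0.0},
        {"hr_modulations": [(1.0, 1.5)]},
        {"bp_light_mean": (100.0, 120.0)},
    ])
    def test_invalid_presets_rejected(self, baseline_preset, bad):
        with pytest.raises(ValueError):
            baseline_preset.replace(**bad)

    def test_hvr_spo2_out_of_range_rejected(self, baseline_preset):
        hp = dict(baseline_preset.hvr_params, spo2_hypoxia=0.0)
        with pytest.raises(ValueError):
            baseline_preset.replace(hvr_params=hp)


class TestDeterminism:
    def test_bp_bit_identical(self, baseline_preset):
        p = baseline_preset.replace(duration_h=1.0)
        a = synth.gen_bp_telemetry(p, 2, fs=100.0)
        b = synth.gen_bp_telemetry(p, 2, fs=100.0)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra["pressure"].values,
                                          rb["pressure"].values)

    def test_sleep_and_hvr_bit_identical(self, baseline_preset):
        kw = dict(duration_h=0.2, fs_eeg=100.0, fs_flow=200.0, fs_spo2=25.0)
        a = synth.gen_sleep_session(baseline_preset, **kw)
        b = synth.gen_sleep_session(baseline_preset, **kw)
        np.testing.assert_array_equal(a["flow"].values, b["flow"].values)
        assert a.annotations["hypnogram"] == b.annotations["hypnogram"]
        ha = synth.gen_hvr_session(baseline_preset, fs_flow=200.0)
        hb = synth.gen_hvr_session(baseline_preset, fs_flow=200.0)
        np.testing.assert_array_equal(ha["spo2"].values, hb["spo2"].values)

    def test_different_seeds_differ(self, baseline_preset):
        a = synth.gen_sleep_session(baseline_preset, duration_h=0.2,
                                    fs_eeg=100.0, fs_flow=200.0,
                                    fs_spo2=25.0)
        b = synth.gen_sleep_session(baseline_preset.replace(seed=99),
                                    duration_h=0.2, fs_eeg=100.0,
                                    fs_flow=200.0, fs_spo2=25.0)
        assert not np.array_equal(a["flow"].values, b["flow"].values)


class TestBPTelemetry:
    def test_degenerate_flat_pulse(self, baseline_preset):
        p = baseline_preset.replace(
            duration_h=1.0, bp_light_mean=(100.0, 99.999),
            bp_dark_mean=(100.0, 99.999), bp_circadian_amplitude=0.0,
            bp_animal_sd=0.0, noise_sd={"bp": 0.0})
        rec = synth.gen_bp_telemetry(p, 1, fs=100.0)[0]
        np.testing.assert_allclose(rec["pressure"].values, 100.0, atol=0.01)
        assert rec.annotations["hourly_bp"][0]["map"] == pytest.approx(
            100.0, abs=0.01)

    def test_ground_truth_phase_means_match_preset(self, baseline_preset):
        p = baseline_preset.replace(duration_h=24.0, bp_animal_sd=0.0)
        rec = synth.gen_bp_telemetry(p, 1, fs=100.0)[0]
        truth = rec.annotations["hourly_bp"]
        light = [h["map"] for h in truth
                 if (h["clock_hour"] - 9) % 24 < 12]
        # circadian sinusoid averages out over the 12 light hours
        assert np.mean(light) == pytest.approx(134.9, abs=0.05)

    def test_nonpositive_duration_rejected(self, baseline_preset):
        with pytest.raises(ValueError):
            synth.gen_bp_telemetry(baseline_preset.replace(duration_h=0.5),
                                   1)


class TestHRSeries:
    def test_constant_without_modulation(self, baseline_preset):
        p = baseline_preset.replace(hr_modulations=[],
                                    noise_sd={"hr": 0.0})
        tr = synth.gen_hr_series(p, duration_s=10.0, fs=50.0)
        np.testing.assert_allclose(tr.values, 600.0)

    def test_artifact_injection(self, baseline_preset):
        p = baseline_preset.replace(hr_modulations=[],
                                    noise_sd={"hr": 0.0})
        clean = synth.gen_hr_series(p, duration_s=30.0, fs=50.0)
        spiked = synth.gen_hr_series(p, [(10.0, 150.0)], duration_s=30.0,
                                     fs=50.0)
        differs = spiked.values != clean.values
        assert np.all(spiked.values[differs] == 150.0)
        assert differs.sum() == int(0.5 * 50)  # default 0.5 s excursion

    def test_energy_placement_of_single_modulation(self, baseline_preset):
        """≥90 % of off-DC beat-interval power within ±0.1 Hz of the
        modulation frequency (direct FFT oracle)."""
        f_mod = 1.0
        p = baseline_preset.replace(hr_modulations=[(f_mod, 0.05)],
                                    noise_sd={"hr": 0.0})
        tr = synth.gen_hr_series(p, duration_s=120.0, fs=50.0)
        interval = 60.0 / tr.values
        x = interval - interval.mean()
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, d=1.0 / 50.0)
        near = np.abs(freqs - f_mod) <= 0.1
        assert spec[near].sum() / spec[1:].sum() >= 0.90


class TestSleepSession:
    def test_zero_rates_give_empty_events(self, baseline_preset):
        p = baseline_preset.replace(apnea_rate=0.0, desat_rate=0.0)
        rec = synth.gen_sleep_session(p, duration_h=0.5, fs_eeg=100.0,
                                      fs_flow=200.0, fs_spo2=25.0)
        assert rec.annotations["events"] == []

    def test_apnea_count_near_poisson_mean(self, psg, baseline_preset):
        stages = psg.annotations["hypnogram"]
        tst_h = sum(s != "WAKE" for s in stages) * 10.0 / 3600.0
        mu = baseline_preset.apnea_rate * tst_h
        n = sum(e["type"] == "APNEA" for e in psg.annotations["events"])
        assert abs(n - mu) <= 3.0 * np.sqrt(mu)

    def test_inserted_apneas_are_deep_reductions(self, psg):
        """Inserted apnea segments carry ≤10 % of surrounding amplitude."""
        flow = psg["flow"]
        for ev in psg.annotations["events"]:
            if ev["type"] != "APNEA":
                continue
            i0 = int(ev["start_s"] * flow.rate)
            i1 = int((ev["start_s"] + ev["duration_s"]) * flow.rate)
            inside = np.percentile(np.abs(flow.values[i0:i1]), 95)
            around = np.percentile(
                np.abs(flow.values[max(0, i0 - int(10 * flow.rate)):i0]), 95)
            assert inside <= 0.10 * around

    def test_breath_volume_matches_preset(self, baseline_preset):
        """Airflow integral over an inspiration equals the stage V_T."""
        p = baseline_preset.replace(
            apnea_rate=0.0, desat_rate=0.0, noise_sd={"flow": 0.0},
            hypnogram_params={"mean_bout_s": {"WAKE": 1.0, "NREM": 1e5,
                                              "REM": 1.0},
                              "p_nrem_to_rem": 0.0})
        rec = synth.gen_sleep_session(p, duration_h=0.1, fs_eeg=100.0,
                                      fs_flow=1000.0, fs_spo2=25.0)
        flow = rec["flow"]
        nrem = [b for b in rec.annotations["breaths"]
                if b["stage"] == "NREM"]
        assert len(nrem) >= 10
        for br in nrem[2:12]:
            i0 = int(round(br["onset_s"] * flow.rate))
            n_i = int(round(br["ti_s"] * flow.rate))
            v = np.trapezoid(flow.values[i0:i0 + n_i + 1], dx=1 / flow.rate)
            assert v == pytest.approx(0.30, rel=0.02)

    def test_negative_apnea_rate_rejected(self, baseline_preset):
        with pytest.raises(ValueError):
            baseline_preset.replace(apnea_rate=-5.0)


class TestHVRSession:
    def test_ground_truth_slope_formula(self, hvr_session):
        truth = hvr_session.annotations["hvr_truth"]
        expected = (2.9 - 1.2) / (97.0 - 63.0)
        assert truth["hvr_ml_min_g_per_pct"] == pytest.approx(expected)

    def test_equal_ventilation_gives_zero_slope(self, baseline_preset):
        hp = dict(baseline_preset.hvr_params, ve_hypoxia_ml_min_g=1.2)
        p = baseline_preset.replace(hvr_params=hp)
        rec = synth.gen_hvr_session(p, fs_flow=200.0)
        assert rec.annotations["hvr_truth"]["hvr_ml_min_g_per_pct"] == 0.0

    def test_spo2_plateaus(self, hvr_session):
        spo2 = hvr_session["spo2"]
        pre = spo2.values[:int(1100 * spo2.rate)]
        post = spo2.values[int(1260 * spo2.rate):]
        assert np.mean(pre) == pytest.approx(97.0, abs=0.1)
        assert np.mean(post) == pytest.approx(63.0, abs=0.1)
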