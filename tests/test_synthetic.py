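"""Generator contracts: dose-response ground truth, coupling placement,
noise structure, determinism, and I/O round trips."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sps

import corticocardiac as cc
from corticocardiac.synthetic import (_pink_noise, clinical_linear_predictor,
                                      load_clinical_config,
                                      load_volunteer_config, save_config)

FIXED_COHORT = dict(hr_intercept_sd=0.0, hr_slope_sd=0.0,
                    rwa_base_sd=0.0, rwa_slope_sd=0.0)


def events(**kw):
    cfg = cc.VolunteerSimConfig(phase_scale=0.25, **kw)
    return cfg, cc.simulate_volunteer_events(cfg)


class TestVolunteerGroundTruth:
    def test_no_coupling_flags_when_kappa_zero(self):
        _, (_, _, _, flags, _, _) = events(seed=3, sw_coupling_prob=0.0)
        assert flags.size > 0 and not flags.any()

    def test_awake_heart_rate_matches_intercept(self):
        # rate-integral oracle: at Ce=0 the zero-mean RR modulation leaves
        # the mean rate at the configured intercept
        cfg, (beats, *_rest) = events(seed=4, **FIXED_COHORT)
        t0, t1 = cfg.phase_window("awake")
        b = beats[(beats >= t0) & (beats < t1)]
        hr = 60.0 / np.diff(b)
        assert abs(hr.mean() - cfg.hr_intercept) < 1.0

    def test_peak_minus_awake_rate_equals_slope_times_ce(self):
        cfg, (beats, *_rest) = events(seed=4, **FIXED_COHORT)
        aw, pk = cfg.phase_window("awake"), cfg.phase_window("peak")
        hr = 60.0 / np.diff(beats)
        mid = beats[:-1] + np.diff(beats) / 2
        m_aw = hr[(mid >= aw[0]) & (mid < aw[1])].mean()
        m_pk = hr[(mid >= pk[0]) & (mid < pk[1])].mean()
        assert m_pk - m_aw == pytest.approx(cfg.hr_slope * cfg.ce_max, abs=1.0)

    def test_coupled_onsets_lag_preceding_beat_exactly(self):
        # zero RR variability: every coupled onset sits at beat + lag
        cfg, (beats, _, onsets, flags, _, _) = events(
            seed=5, sw_coupling_prob=1.0, rsa_amp_base=0.0, rsa_amp_slope=0.0,
            lf_amp=0.0, rr_noise_ms=0.0, **FIXED_COHORT)
        assert flags.all()
        prev = beats[np.searchsorted(beats, onsets, side="right") - 1]
        np.testing.assert_allclose(onsets - prev, cfg.sw_coupling_lag, atol=1e-9)

    def test_truth_rmssd_shrinks_with_concentration(self):
        cfg, (beats, *_rest) = events(seed=6, **FIXED_COHORT)
        assert cfg.rsa_amp_slope < 0
        bs = cc.BeatSeries(beats, np.zeros_like(beats))
        rms_awake = cc.rmssd(bs, cfg.phase_window("awake"))
        rms_peak = cc.rmssd(bs, cfg.phase_window("peak"))
        assert rms_awake > rms_peak

    def test_rr_bounds_rejected(self):
        with pytest.raises(ValueError):
            cc.VolunteerSimConfig(hr_intercept=260.0)
        cfg = cc.VolunteerSimConfig(phase_scale=0.125, seed=1,
                                    rsa_amp_base=900.0, **FIXED_COHORT)
        with pytest.raises(ValueError, match="RR"):
            cc.simulate_volunteer_events(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            cc.VolunteerSimConfig(sw_coupling_prob=1.5)
        with pytest.raises(ValueError):
            cc.VolunteerSimConfig(fs_ecg=100.0)
        with pytest.raises(ValueError):
            cc.VolunteerSimConfig(phase_durations=(0.0, 1.0, 1.0, 1.0))


class TestVolunteerTraces:
    def test_recording_invariants(self, vol_default):
        rec = vol_default["rec"]
        assert np.all(np.diff(rec.truth_beats) > 0)
        assert np.all(np.diff(rec.truth_sw_onsets) > 0)
        assert np.all(np.isfinite(rec.ecg.samples))
        assert np.all(np.isfinite(rec.eeg.samples))
        gaps = np.diff(rec.truth_beats)
        assert gaps.min() > 0.24 and gaps.max() < 6.0

    def test_eeg_background_follows_configured_spectral_slope(self):
        alpha = 1.0
        x = _pink_noise(200 * 100, alpha, 12.0, 100.0, np.random.default_rng(5))
        f, p = sps.welch(x, fs=100.0, nperseg=4096)
        m = (f >= 1.0) & (f <= 30.0)
        slope = np.polyfit(np.log(f[m]), np.log(p[m]), 1)[0]
        assert abs(-slope - alpha) < 0.2

    def test_seed_reproducibility_bit_identical(self):
        a = cc.simulate_volunteer(cc.VolunteerSimConfig(phase_scale=0.125, seed=9))
        b = cc.simulate_volunteer(cc.VolunteerSimConfig(phase_scale=0.125, seed=9))
        assert np.array_equal(a.ecg.samples, b.ecg.samples)
        assert np.array_equal(a.eeg.samples, b.eeg.samples)
        assert np.array_equal(a.truth_beats, b.truth_beats)
        assert np.array_equal(a.truth_sw_onsets, b.truth_sw_onsets)


class TestClinical:
    def test_noise_free_equals_linear_predictor(self):
        cfg = cc.ClinicalSimConfig(seed=1, n_patients=5, duration=600.0,
                                   residual_sd=0.0, random_intercept_sd=0.0,
                                   artifact_rate=0.0)
        tab = cc.simulate_clinical(cfg)
        np.testing.assert_allclose(
            tab["hr_bpm"], clinical_linear_predictor(tab, cfg.coeffs), atol=1e-9)

    def test_artifacts_injected_off_scale(self):
        tab = cc.simulate_clinical(cc.ClinicalSimConfig(seed=2, artifact_rate=30.0,
                                                        n_patients=5))
        hr = tab["hr_bpm"]
        assert ((hr > 250) | (hr < 10)).any()

    def test_patient_cardinality(self):
        tab = cc.simulate_clinical(cc.ClinicalSimConfig(seed=3, duration=300.0))
        assert tab["patient_id"].nunique() == 96

    def test_clinical_determinism(self):
        cfg = dict(seed=4, n_patients=4, duration=600.0)
        a = cc.simulate_clinical(cc.ClinicalSimConfig(**cfg))
        b = cc.simulate_clinical(cc.ClinicalSimConfig(**cfg))
        assert a.equals(b)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            cc.ClinicalSimConfig(n_patients=1)
        with pytest.raises(ValueError):
            cc.ClinicalSimConfig(residual_sd=-1.0)
        with pytest.raises(ValueError):
            cc.ClinicalSimConfig(coeffs=np.ones(5))


class TestIo:
    def test_volunteer_config_round_trip(self, tmp_path):
        cfg = cc.VolunteerSimConfig(seed=7, sw_coupling_prob=0.8, phase_scale=0.5)
        p = tmp_path / "cfg.yaml"
        save_config(cfg, p)
        assert load_volunteer_config(p) == cfg

    def test_clinical_config_round_trip(self, tmp_path):
        cfg = cc.ClinicalSimConfig(seed=8, n_patients=12)
        p = tmp_path / "cfg.yaml"
        save_config(cfg, p)
        loaded = load_clinical_config(p)
        assert loaded.n_patients == 12 and loaded.seed == 8
        np.testing.assert_array_equal(loaded.coeffs, cfg.coeffs)

    def test_recording_round_trip(self, tmp_path):
        cfg = cc.VolunteerSimConfig(phase_scale=0.05, seed=10)
        rec = cc.simulate_volunteer(cfg)
        cc.save_recording(rec, tmp_path / "rec")
        back = cc.load_recording(tmp_path / "rec")
        np.testing.assert_allclose(back.ecg.samples, rec.ecg.samples, atol=1e-3)
        np.testing.assert_allclose(back.truth_beats, rec.truth_beats, atol=1e-4)
        np.testing.assert_array_equal(back.truth_coupled_flags,
                                      rec.truth_coupled_flags)
        assert back.config == cfg
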