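"""RS intervals, proportional Shannon entropy, surrogate calibration, and
time-locked averaging."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import corticocardiac as cc


def entropy_events(kappa: float, seed: int, **kw):
    cfg = cc.VolunteerSimConfig(phase_scale=0.25, seed=seed,
                                sw_coupling_prob=kappa, **kw)
    beats, rwa, onsets, *_ = cc.simulate_volunteer_events(cfg)
    bs = cc.BeatSeries(beats, rwa)
    return cfg, bs, onsets


class TestRsIntervals:
    def test_offsets_by_hand(self):
        beats = cc.BeatSeries(np.arange(0.0, 10.0), np.zeros(10))
        rs = cc.rs_intervals(beats, np.array([4.45]))
        assert rs.rs_minus_1[0] == pytest.approx(0.45)
        assert rs.following[0, 0] == pytest.approx(0.55)
        np.testing.assert_allclose(rs.preceding[0], [0.45, 1.45, 2.45, 3.45])
        np.testing.assert_allclose(rs.following[0], [0.55, 1.55, 2.55, 3.55])

    def test_onset_on_beat_counts_as_preceding(self):
        beats = cc.BeatSeries(np.arange(0.0, 10.0), np.zeros(10))
        rs = cc.rs_intervals(beats, np.array([5.0]))
        assert rs.rs_minus_1[0] == 0.0

    def test_edge_waves_skipped(self):
        beats = cc.BeatSeries(np.arange(0.0, 10.0), np.zeros(10))
        rs = cc.rs_intervals(beats, np.array([1.5, 5.5, 8.5]))
        assert len(rs) == 1 and rs.wave_onsets[0] == 5.5

    def test_nearest_mode_keeps_closest_eight(self):
        beats = cc.BeatSeries(np.arange(0.0, 20.0), np.zeros(20))
        rs = cc.rs_intervals(beats, np.array([10.2]), mode="nearest")
        assert rs.rs_minus_1[0] == pytest.approx(0.2)
        kept = np.isfinite(np.concatenate([rs.preceding[0], rs.following[0]]))
        assert kept.sum() == 8

    def test_coupled_simulation_rs1_equals_lag(self):
        cfg, bs, onsets = entropy_events(
            1.0, seed=3, rsa_amp_base=0.0, rsa_amp_slope=0.0, lf_amp=0.0,
            rr_noise_ms=0.0, hr_intercept_sd=0.0, hr_slope_sd=0.0)
        rs = cc.rs_intervals(bs, onsets)
        np.testing.assert_allclose(rs.rs_minus_1, cfg.sw_coupling_lag, atol=1e-9)


class TestProportionalEntropy:
    def test_single_bin_zero(self):
        assert cc.proportional_entropy(np.full(40, 0.05), 0.0, 1.0) == 0.0

    def test_uniform_bins_one(self):
        vals = np.repeat(np.arange(10) / 10.0 + 0.05, 4)
        assert cc.proportional_entropy(vals, 0.0, 1.0) == pytest.approx(1.0)

    def test_thirty_ten_split(self):
        vals = np.concatenate([np.full(30, 0.05), np.full(10, 0.55)])
        # -(0.75 ln 0.75 + 0.25 ln 0.25) / ln 10
        assert cc.proportional_entropy(vals, 0.0, 1.0) == pytest.approx(
            0.2442, abs=5e-4)

    def test_out_of_range_excluded_empty_is_nan(self):
        assert np.isnan(cc.proportional_entropy(np.array([5.0]), 0.0, 1.0))

    def test_invalid_limits(self):
        with pytest.raises(ValueError):
            cc.proportional_entropy(np.array([0.5]), 1.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(0.01, 0.99), min_size=5, max_size=60),
           hst.floats(0.1, 50.0), hst.floats(-10.0, 10.0))
    def test_affine_invariance(self, vals, scale, shift):
        v = np.asarray(vals)
        a = cc.proportional_entropy(v, 0.0, 1.0)
        b = cc.proportional_entropy(v * scale + shift, shift, scale + shift)
        assert a == pytest.approx(b, abs=1e-12)


class TestWindowedEntropy:
    def test_perfect_coupling_zero_entropy(self):
        _, bs, onsets = entropy_events(
            1.0, seed=4, rsa_amp_base=0.0, rsa_amp_slope=0.0, lf_amp=0.0,
            rr_noise_ms=0.0, hr_intercept_sd=0.0, hr_slope_sd=0.0)
        ent = cc.windowed_entropy(cc.rs_intervals(bs, onsets), bs)
        assert ent.subject_mean_shp == 0.0

    def test_uncoupled_entropy_near_finite_sample_null(self):
        # Monte-Carlo null: 40 uniform draws in 10 bins
        rng = np.random.default_rng(0)
        draws = rng.random((4000, 40))
        shps = []
        for row in draws:
            c = np.bincount((row * 10).astype(int), minlength=10)
            p = c[c > 0] / 40.0
            shps.append(-np.sum(p * np.log(p)) / np.log(10))
        null_mean = np.mean(shps)
        _, bs, onsets = entropy_events(0.0, seed=5)
        ent = cc.windowed_entropy(cc.rs_intervals(bs, onsets), bs)
        assert ent.subject_mean_shp == pytest.approx(null_mean, abs=0.04)

    def test_coupled_below_uncoupled_on_matched_seed(self):
        for seed in (6, 7):
            _, bs1, on1 = entropy_events(1.0, seed=seed)
            _, bs0, on0 = entropy_events(0.0, seed=seed)
            e1 = cc.windowed_entropy(cc.rs_intervals(bs1, on1), bs1)
            e0 = cc.windowed_entropy(cc.rs_intervals(bs0, on0), bs0)
            assert e1.subject_mean_shp < e0.subject_mean_shp

    def test_monotone_in_coupling_probability(self):
        # 20-seed averages over the kappa grid are non-increasing
        kappas = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for kappa in kappas:
            vals = []
            for seed in range(20):
                _, bs, onsets = entropy_events(kappa, seed=100 + seed)
                ent = cc.windowed_entropy(cc.rs_intervals(bs, onsets), bs)
                vals.append(ent.subject_mean_shp)
            means.append(np.nanmean(vals))
        assert all(np.diff(means) <= 0)

    def test_too_few_waves_gives_nan(self):
        bs = cc.BeatSeries(np.arange(0.0, 100.0), np.zeros(100))
        ent = cc.windowed_entropy(cc.rs_intervals(bs, np.array([50.2])), bs)
        assert np.isnan(ent.subject_mean_shp) and ent.n_windows == 0

    def test_window_probabilities_sum_to_one(self, vol_coupled):
        beats, waves = vol_coupled["beats"], vol_coupled["waves"]
        ent = cc.windowed_entropy(cc.rs_intervals(beats, waves), beats)
        sums = np.nansum(ent.bin_probabilities, axis=1)
        np.testing.assert_allclose(sums[np.isfinite(ent.window_entropies)], 1.0)
        assert np.all((ent.window_entropies >= 0) & (ent.window_entropies <= 1))


class TestSurrogates:
    def test_canonical_threshold_reproduced(self):
        cal = cc.surrogate_threshold(seed=12)
        assert cal.threshold == pytest.approx(0.970, abs=0.003)

    def test_threshold_matches_chi2_approximation(self):
        cal = cc.surrogate_threshold(seed=13)
        assert cal.threshold == pytest.approx(cc.entropy_threshold_chi2(),
                                              abs=0.003)

    def test_degenerate_identical_series_entropy_zero(self):
        assert cc.proportional_entropy(np.full(200, 0.3), 0.0, 1.0) == 0.0

    def test_windowed_mode_threshold_below_single_mode(self):
        single = cc.surrogate_threshold(n_surrogates=2000, seed=14)
        windowed = cc.surrogate_threshold(n_surrogates=1000, seed=14,
                                          mode="windowed")
        assert windowed.threshold < single.threshold

    def test_decision_rule_directions(self, vol_coupled):
        beats, waves = vol_coupled["beats"], vol_coupled["waves"]
        ent = cc.windowed_entropy(cc.rs_intervals(beats, waves), beats)
        assert ent.subject_mean_shp < 0.970
        windowed = cc.surrogate_threshold(n_surrogates=1000, seed=15,
                                          mode="windowed")
        _, bs0, on0 = entropy_events(0.0, seed=16)
        e0 = cc.windowed_entropy(cc.rs_intervals(bs0, on0), bs0)
        assert e0.subject_mean_shp >= windowed.threshold

    def test_surrogate_determinism_and_validation(self):
        a = cc.surrogate_threshold(n_surrogates=1000, seed=1)
        b = cc.surrogate_threshold(n_surrogates=1000, seed=1)
        assert a.threshold == b.threshold
        with pytest.raises(ValueError):
            cc.surrogate_threshold(n_surrogates=10)


class TestTimeLockedAverage:
    def test_coupled_cohort_peak_at_configured_lag(self, vol_coupled):
        cfg, rec, eeg, waves = (vol_coupled[k]
                                for k in ("cfg", "rec", "eeg", "waves"))
        tla = cc.time_locked_average(rec.ecg, eeg, waves)
        assert tla.peak_lag == pytest.approx(-cfg.sw_coupling_lag, abs=0.030)
        assert tla.n_waves >= 10
        np.testing.assert_allclose(tla.ecg_lags[0], -2.0)
        np.testing.assert_allclose(tla.ecg_lags[-1], 2.0)

    def test_eeg_average_crosses_zero_downward_at_lock(self, vol_coupled):
        rec, eeg, waves = (vol_coupled[k] for k in ("rec", "eeg", "waves"))
        tla = cc.time_locked_average(rec.ecg, eeg, waves)
        i0 = int(np.argmin(np.abs(tla.eeg_lags)))
        after = tla.eeg_mean[i0 + 2: i0 + int(0.3 * 100)]
        before = tla.eeg_mean[i0 - int(0.2 * 100): i0 - 2]
        assert after.mean() < 0 < before.mean()

    def test_uncoupled_average_shrinks_with_wave_count(self):
        cfg = cc.VolunteerSimConfig(phase_scale=0.25, seed=21,
                                    sw_coupling_prob=0.0)
        rec = cc.simulate_volunteer(cfg)
        eeg = cc.preprocess_eeg(rec.eeg)
        onsets = rec.truth_sw_onsets
        chunk = 20
        amps = []
        for start in range(0, onsets.size - chunk + 1, chunk):
            sub = cc.time_locked_average(rec.ecg, eeg,
                                         onsets[start: start + chunk])
            amps.append(np.std(sub.ecg_band_mean))
        many = cc.time_locked_average(rec.ecg, eeg, onsets)
        ratio = np.mean(amps) / np.std(many.ecg_band_mean)
        expected = np.sqrt(many.n_waves / chunk)
        assert ratio == pytest.approx(expected, rel=0.5)

    def test_too_few_waves_error(self, vol_coupled):
        rec, eeg = vol_coupled["rec"], vol_coupled["eeg"]
        with pytest.raises(ValueError):
            cc.time_locked_average(rec.ecg, eeg, np.array([100.0, 200.0]))
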