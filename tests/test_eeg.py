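"""Wavelet decomposition, baseline handling, regression and cluster stats."""

import numpy as np
import pandas as pd
import pytest

from bisectlab import eeg, synth

SR = 250.0
FREQS = eeg.log_freqs(10, 40, 40)


def _epochs_from_signal(signal, n_trials=4, meta=None):
    """signal: (n_times,) replicated across trials, single channel."""
    data = np.tile(signal[None, :, None], (1, 1, n_trials))
    meta = meta if meta is not None else pd.DataFrame(
        {"duration_s": np.linspace(0.3, 0.9, n_trials),
         "prior_duration_s": np.linspace(0.3, 0.9, n_trials)})
    return eeg.Epochs(data=data, sample_rate=SR, window=(-0.4, 1.0),
                      trial_meta=meta)


def _times():
    return -0.4 + np.arange(int(1.4 * SR)) / SR


class TestMorlet:
    def test_pure_tone_peaks_at_nearest_bin(self):
        ep = _epochs_from_signal(np.sin(2 * np.pi * 20 * _times()))
        tf = eeg.morlet_tf(ep, FREQS)
        mean_pow = tf.power.mean(axis=(0, 2))
        assert mean_pow.argmax() == np.abs(FREQS - 20).argmin()

    def test_power_scales_with_amplitude_squared(self):
        sig = np.sin(2 * np.pi * 20 * _times())
        tf1 = eeg.morlet_tf(_epochs_from_signal(sig), FREQS)
        tf3 = eeg.morlet_tf(_epochs_from_signal(3 * sig), FREQS)
        inner = tf1.valid
        ratio = tf3.power[0][inner] / tf1.power[0][inner]
        assert np.allclose(ratio, 9.0, rtol=1e-6)

    def test_amplitude_step_quadruples_power(self):
        t = _times()
        sig = np.sin(2 * np.pi * 20 * t) * np.where(t < 0.3, 1.0, 2.0)
        tf = eeg.morlet_tf(_epochs_from_signal(sig), FREQS)
        fi = np.abs(FREQS - 20).argmin()
        pre = tf.power[0, fi, (t > -0.2) & (t < 0.1)].mean()
        post = tf.power[0, fi, (t > 0.5) & (t < 0.8)].mean()
        assert post / pre == pytest.approx(4.0, rel=0.05)

    def test_two_tone_ridges_match_stft_oracle(self):
        from scipy.signal import stft

        t = _times()
        sig = np.sin(2 * np.pi * 12 * t) + 0.8 * np.sin(2 * np.pi * 30 * t)
        tf = eeg.morlet_tf(_epochs_from_signal(sig), FREQS)
        mean_pow = tf.power.mean(axis=(0, 2))
        lo_peak = FREQS[:20][mean_pow[:20].argmax()]
        hi_peak = FREQS[20:][mean_pow[20:].argmax()]
        f, _, Z = stft(sig, fs=SR, nperseg=128)
        spec = np.abs(Z).mean(axis=1)
        band = (f >= 8) & (f <= 45)
        peaks = f[band][np.argsort(spec[band])[-2:]]
        assert min(abs(lo_peak - p) for p in peaks) < 1.5
        assert min(abs(hi_peak - p) for p in peaks) < 1.5

    def test_epoch_too_short_names_limiting_frequency(self):
        short = eeg.Epochs(
            data=np.zeros((1, 50, 2)), sample_rate=SR, window=(-0.05, 0.15),
            trial_meta=pd.DataFrame({"duration_s": [0.3, 0.5]}))
        with pytest.raises(ValueError, match="Hz"):
            eeg.morlet_tf(short, FREQS)

    def test_cycle_schedule_convention(self):
        c = eeg.wavelet_cycles(np.array([10.0, 20.0, 40.0]), 3.0, 0.5)
        assert c[0] == pytest.approx(3.0)
        # at double the base frequency: 3 + 0.5*(6-3) = 4.5
        assert c[1] == pytest.approx(4.5)
        assert c[2] == pytest.approx(7.5)


class TestBaseline:
    def test_stationary_signal_divides_to_one(self):
        sig = np.sin(2 * np.pi * 20 * _times())
        tf = eeg.morlet_tf(_epochs_from_signal(sig), FREQS)
        bl = eeg.baseline_divide(tf)
        fi = np.abs(FREQS - 20).argmin()
        interior = tf.valid[fi]
        assert np.allclose(bl.power[0, fi, interior], 1.0, rtol=0.05)

    def test_event_locked_doubling_gives_ratio_four(self):
        t = _times()
        sig = np.sin(2 * np.pi * 20 * t) * np.where(t < 0.1, 1.0, 2.0)
        tf = eeg.morlet_tf(_epochs_from_signal(sig), FREQS)
        bl = eeg.baseline_divide(tf)
        fi = np.abs(FREQS - 20).argmin()
        assert bl.power[0, fi, (t > 0.5) & (t < 0.8)].mean() == pytest.approx(
            4.0, rel=0.05)

    def test_single_trial_division_resists_outlier_trial(self):
        """One extreme-power trial distorts the average-baseline estimate
        but not the single-trial-division estimate."""
        rng = np.random.default_rng(4)
        n_trials = 20
        t = _times()
        base = rng.standard_normal((1, len(t), n_trials))
        base[..., 0] *= 40.0  # one massive trial
        ep = eeg.Epochs(data=base, sample_rate=SR, window=(-0.4, 1.0),
                        trial_meta=pd.DataFrame(
                            {"duration_s": np.resize(np.geomspace(.3, .9, 7),
                                                     n_trials)}))
        tf = eeg.morlet_tf(ep, FREQS)
        single = eeg.baseline_divide(tf)
        sel = (tf.times >= -0.2) & (tf.times <= 0)
        avg_base = tf.power[:, :, sel].mean(axis=(0, 2))  # averaged baseline
        averaged = tf.power / avg_base[None, :, None]
        # ordinary trials: single-trial division stays near 1, the
        # average-then-divide version is crushed by the outlier
        interior = tf.valid[np.abs(FREQS - 20).argmin()]
        s = single.power[1:, :, interior].mean()
        a = averaged[1:, :, interior].mean()
        assert abs(s - 1.0) < 0.5
        assert a < 0.1

    def test_window_outside_epoch_rejected(self):
        tf = eeg.morlet_tf(_epochs_from_signal(np.sin(2 * np.pi * 20 * _times())),
                           FREQS)
        with pytest.raises(ValueError):
            eeg.baseline_divide(tf, window=(-2.0, -1.5))


class TestRegression:
    def _tf_with_slope(self, slope, seed, n_trials=80):
        rng = np.random.default_rng(seed)
        d = np.resize(np.geomspace(0.3, 0.9, 7), n_trials)
        power = (2.0 + slope * d)[:, None, None] \
            + 0.5 * rng.standard_normal((n_trials, 10, 30))
        power = np.clip(power, 0, None)
        return eeg.TFMap(power=power, freqs=np.arange(10, 20.0),
                         times=np.linspace(0, 1, 30),
                         trial_meta=pd.DataFrame(
                             {"duration_s": d, "prior_duration_s": d})), d

    def test_known_slope_recovered(self):
        slopes = []
        for s in range(50):
            tf, _ = self._tf_with_slope(2.0, s)
            slopes.append(eeg.duration_regression(tf).mean())
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 2.0) < 3 * se

    def test_null_slope_near_zero(self):
        tf, _ = self._tf_with_slope(0.0, 99)
        assert abs(eeg.duration_regression(tf).mean()) < 0.2

    def test_shuffled_regressor_destroys_slope(self):
        tf, d = self._tf_with_slope(2.0, 7)
        rng = np.random.default_rng(0)
        means = [
            eeg.duration_regression(tf, values=rng.permutation(d)).mean()
            for _ in range(20)
        ]
        assert abs(np.mean(means)) < 0.3

    def test_constant_regressor_rejected(self):
        tf, _ = self._tf_with_slope(1.0, 1)
        with pytest.raises(ValueError):
            eeg.duration_regression(tf, values=np.full(80, 0.52))


class TestClusterPermutation:
    def test_all_zero_maps_give_no_clusters(self):
        res = eeg.cluster_permutation(np.zeros((5, 8, 12)), n_perm=100, seed=0)
        assert len(res.p_values) == 0
        assert not res.significant.any()

    def test_implanted_region_detected(self):
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((10, 20, 30))
        maps[:, 5:12, 10:20] += 1.5
        res = eeg.cluster_permutation(maps, n_perm=500, seed=2)
        assert (res.p_values < 0.05).any()
        best = res.cluster_stats.iloc[res.p_values.argmin()]
        assert best["sign"] == 1
        # detected cluster overlaps the implanted frequency rows
        assert best["freq_lo_idx"] <= 11 and best["freq_hi_idx"] >= 5

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(3)
        maps = rng.standard_normal((8, 10, 15)) + 0.4
        r1 = eeg.cluster_permutation(maps, n_perm=200, seed=5)
        r2 = eeg.cluster_permutation(-maps, n_perm=200, seed=5)
        np.testing.assert_allclose(r1.stat_map, -r2.stat_map, atol=1e-12)

    def test_matches_mne_cluster_test_on_fixture(self):
        """Cross-check observed clusters against the reference MNE
        implementation (same forming threshold, size statistic)."""
        from mne.stats import permutation_cluster_1samp_test
        from scipy import stats as sps

        rng = np.random.default_rng(8)
        maps = rng.standard_normal((12, 15, 25))
        maps[:, 3:7, 5:15] += 1.2
        t_crit = sps.t.ppf(1 - 0.025, 11)
        ours = eeg.cluster_permutation(maps, n_perm=500, seed=1)
        _, clusters, _, _ = permutation_cluster_1samp_test(
            maps, threshold=t_crit, n_permutations=100, tail=0,
            adjacency=None, seed=1, out_type="mask", verbose=False)
        mne_sizes = sorted(int(np.sum(c)) for c in clusters)
        our_sizes = sorted(int(s) for s in ours.cluster_stats["stat"])
        assert our_sizes == mne_sizes

    def test_low_perm_count_warns(self):
        with pytest.warns(UserWarning):
            eeg.cluster_permutation(np.random.default_rng(0).standard_normal(
                (4, 5, 5)), n_perm=10, alpha=0.05, seed=0)


class TestContrasts:
    def test_equal_conditions_yield_no_clusters(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((6, 10, 12))
        diff = eeg.condition_contrast(a, a.copy())
        res = eeg.cluster_permutation(diff, n_perm=100, seed=0)
        assert len(res.p_values) == 0

    def test_swapping_conditions_negates_stat_map(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((6, 10, 12))
        b = rng.standard_normal((6, 10, 12))
        d1 = eeg.condition_contrast(a, b)
        d2 = eeg.condition_contrast(b, a)
        np.testing.assert_allclose(d1, -d2)

    def test_implanted_band_increase_detected(self):
        """A band-limited power increase in condition A only shows up as a
        positive cluster in the paired contrast."""
        rng = np.random.default_rng(6)
        b = rng.standard_normal((10, 20, 30))
        a = rng.standard_normal((10, 20, 30))
        a[:, 8:13, 12:24] += 1.5  # "high beta" band rows
        res = eeg.cluster_permutation(eeg.condition_contrast(a, b),
                                      n_perm=500, seed=3)
        assert (res.p_values < 0.05).any()
        best = res.cluster_stats.iloc[res.p_values.argmin()]
        assert best["sign"] == 1

    def test_subject_mismatch_rejected(self):
        x = np.zeros((3, 4, 5))
        with pytest.raises(ValueError):
            eeg.condition_contrast(x, x, subjects_a=["a", "b", "c"],
                                   subjects_b=["a", "c", "b"])

    def test_choice_contrast_requires_both_categories(self):
        tf = eeg.TFMap(power=np.ones((4, 3, 3)), freqs=np.arange(3.0),
                       times=np.arange(3.0))
        with pytest.raises(ValueError):
            eeg.choice_contrast_maps(tf, np.array(["long"] * 4))
        out = eeg.choice_contrast_maps(
            tf, np.array(["long", "short", "long", "short"]))
        np.testing.assert_allclose(out, 0.0)
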