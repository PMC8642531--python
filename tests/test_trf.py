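import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import steerdecode as sd
from steerdecode import synth, trf
from steerdecode.trf import (DEFAULT_ANTICIPATIONS, LagWindow,
                             anticipation_to_window, cross_validated_fit,
                             fold_slices, lag_design, latency_to_lags,
                             pearson_r, ridge_solve)


def oracle_ridge(D, y, lam):
    """Independent normal-equations solution (centered, identity penalty)."""
    Dc = D - D.mean(axis=0)
    yc = y - y.mean(axis=0)
    w = np.linalg.solve(Dc.T @ Dc + lam * np.eye(D.shape[1]), Dc.T @ yc)
    return w, y.mean(axis=0) - D.mean(axis=0) @ w


class TestLagDesign:
    def test_zero_window_is_identity(self):
        x = np.random.default_rng(0).standard_normal(100)
        D = lag_design(x, LagWindow(0, 0), 100)
        np.testing.assert_array_equal(D[:, 0], x)

    def test_impulse_shifts(self):
        x = np.zeros(50)
        x[10] = 1.0
        D = lag_design(x, LagWindow(0, 0.02), 100)
        assert D.shape == (50, 3)
        for j, sample in enumerate([10, 11, 12]):
            col = D[:, j]
            assert col[sample] == 1.0 and col.sum() == 1.0

    def test_column_order_channel_major(self):
        x = np.random.default_rng(1).standard_normal((60, 2))
        D = lag_design(x, LagWindow(-0.01, 0.01), 100)
        assert D.shape == (60, 6)
        np.testing.assert_array_equal(D[:, 1], x[:, 0])  # channel 0, lag 0
        np.testing.assert_array_equal(D[:, 4], x[:, 1])  # channel 1, lag 0

    def test_window_longer_than_signal_errors(self):
        with pytest.raises(ValueError):
            lag_design(np.zeros(5), LagWindow(0, 1.0), 100)


class TestRidgeSolve:
    @pytest.mark.parametrize("lam", [0.0, 1.0, 100.0])
    def test_matches_normal_equations(self, lam):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((500, 3))
        D = lag_design(x, LagWindow(0, 0.09), 100)
        y = rng.standard_normal(500)
        w, b = ridge_solve(D, y, lam)
        w0, b0 = oracle_ridge(D, y[:, None], lam)
        np.testing.assert_allclose(w, w0[:, 0], atol=1e-8)
        np.testing.assert_allclose(b, b0[0], atol=1e-8)

    def test_huge_lambda_shrinks_weights(self):
        rng = np.random.default_rng(3)
        D = rng.standard_normal((200, 5))
        w, _ = ridge_solve(D, rng.standard_normal(200), 1e12)
        assert np.abs(w).max() < 1e-6

    def test_noiseless_recovery(self):
        rng = np.random.default_rng(4)
        D = rng.standard_normal((300, 4))
        w0 = np.array([1.0, -2.0, 0.5, 3.0])
        y = D @ w0 + 0.7
        w, b = ridge_solve(D, y, 1e-10)
        np.testing.assert_allclose(w, w0, atol=1e-6)
        np.testing.assert_allclose(b, 0.7, atol=1e-6)

    def test_singular_at_lambda_zero_warns(self):
        D = np.ones((50, 3))
        with pytest.warns(UserWarning):
            ridge_solve(D, np.random.default_rng(5).standard_normal(50), 0.0)


class TestPearson:
    def test_perfect_and_inverse(self):
        x = np.random.default_rng(6).standard_normal(100)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_orthogonal_sinusoids(self):
        t = np.arange(1000) / 100
        assert abs(pearson_r(np.sin(2 * np.pi * t), np.cos(2 * np.pi * t))) < 1e-6

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(10), np.arange(10.0))


class TestCrossValidatedFit:
    def test_noiseless_convolution_high_r(self):
        rng = np.random.default_rng(7)
        s = sd.generate_steering(120, 50, 0.5, seed=7).values
        k = synth.make_kernel([-0.5], [0.1], [1.0], (-1.0, 0.2), 50)
        y = synth.apply_kernel(s, k, (-1.0, 0.2), 50)
        _, cv = cross_validated_fit(s, y, LagWindow(-1.0, 0.2), 50,
                                    mode="global", n_folds=5)
        assert cv.mean_r > 0.99

    def test_unrelated_signals_low_r(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(6000)
        y = rng.standard_normal(6000)
        _, cv = cross_validated_fit(x, y, LagWindow(-0.1, 0.1), 100,
                                    mode="global", n_folds=5)
        assert abs(cv.mean_r) < 0.1

    def test_fold_boundaries_contiguous_cover(self):
        bounds = fold_slices(1003, 10)
        assert bounds[0][0] == 0 and bounds[-1][1] == 1003
        sizes = [hi - lo for lo, hi in bounds]
        assert max(sizes) - min(sizes) <= 1
        for (a, b), (c, d) in zip(bounds[:-1], bounds[1:]):
            assert b == c

    def test_two_fold_cv_equals_direct_ridge(self):
        """Oracle equivalence: CV at fixed lambda with few folds equals
        brute-force per-half ridge solutions."""
        rng = np.random.default_rng(9)
        x = rng.standard_normal(600)
        y = rng.standard_normal(600) + 0.3 * x
        lam = 10.0
        win = LagWindow(-0.05, 0.05)
        _, cv = cross_validated_fit(x, y, win, 100, lambda_grid=[lam],
                                    n_folds=3, mode="global",
                                    standardize=False)
        D = lag_design(x, win, 100)
        bounds = fold_slices(600, 3)
        for k, (lo, hi) in enumerate(bounds):
            train = np.ones(600, dtype=bool)
            train[lo:hi] = False
            w, b = oracle_ridge(D[train], y[train, None], lam)
            pred = D[lo:hi] @ w[:, 0] + b[0]
            assert cv.fold_r[k] == pytest.approx(pearson_r(pred, y[lo:hi]),
                                                 abs=1e-8)

    def test_too_few_folds_errors(self):
        with pytest.raises(ValueError):
            cross_validated_fit(np.zeros(100), np.zeros(100),
                                LagWindow(0, 0), 100, n_folds=2)


class TestEncoder:
    def test_recovers_kernel_peak(self, noiseless_session):
        sess, gt = noiseless_session
        model, cv = sd.fit_encoder(sess.steering.values, sess.eeg,
                                   LagWindow(-1.5, 0.5), sess.fs,
                                   mode="global", n_folds=5)
        assert model.weights.shape == (model.window.n_lags(sess.fs), 1,
                                       gt.n_channels)
        lags = model.window.lags(sess.fs)
        for n in range(gt.n_channels):
            if np.abs(gt.kernels[n]).max() == 0:
                continue
            est = model.weights[:, 0, n]
            true_pk = lags[np.argmax(np.abs(gt.kernels[n]))]
            est_pk = lags[np.argmax(np.abs(est))]
            assert abs(est_pk - true_pk) <= 2
            assert np.corrcoef(gt.kernels[n], est)[0, 1] > 0.95

    def test_zero_eeg_gives_near_zero_weights(self):
        s = sd.generate_steering(60, 25, 0.5, seed=10).values
        eeg = np.zeros((s.size, 3))
        model, _ = sd.fit_encoder(s, eeg, LagWindow(-0.5, 0.5), 25,
                                  lambda_grid=[1.0], mode="global", n_folds=5)
        assert np.abs(model.weights).max() < 1e-8


class TestAnticipationWindows:
    @pytest.mark.parametrize("a,expected", [
        (1.2, (-2.7, -1.2)),
        (0.0, (-1.5, 0.0)),
        (12.0, (-13.5, -12.0)),
    ])
    def test_window_rule(self, a, expected):
        w = anticipation_to_window(a)
        assert (w.tmin_s, w.tmax_s) == pytest.approx(expected)

    def test_negative_anticipation_errors(self):
        with pytest.raises(ValueError):
            anticipation_to_window(-0.5)

    def test_latency_to_lags_sign_flip(self):
        w = latency_to_lags(anticipation_to_window(1.2))
        assert (w.tmin_s, w.tmax_s) == pytest.approx((1.2, 2.7))

    def test_default_list_has_13_entries(self):
        assert len(DEFAULT_ANTICIPATIONS) == 13

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            trf.anticipation_sweep(np.zeros((100, 2)), np.zeros(100), [])


@pytest.fixture(scope="module")
def decoding_session():
    gt = sd.default_ground_truth(n_channels=6, fs=25, noise_sd=1.0, seed=23,
                                 kernel_window=(-1.0, -0.3),
                                 bump_centers_s=(-0.75, -0.45),
                                 bump_widths_s=(0.1, 0.07),
                                 loaded_fraction=0.6)
    sess, gt = sd.generate_session(gt, 300, 25, seed=24)
    return sess, gt


class TestDecoder:
    def test_anticipation_degrades_decoding(self, decoding_session):
        sess, _ = decoding_session
        _, cv0 = sd.fit_decoder(sess.eeg, sess.steering.values, 0.0, 1.5,
                                sess.fs, mode="global")
        _, cv3 = sd.fit_decoder(sess.eeg, sess.steering.values, 3.0, 1.5,
                                sess.fs, mode="global")
        assert cv0.mean_r > cv3.mean_r
        assert cv0.mean_r > 0.5

    def test_sweep_trend_negative(self, decoding_session):
        from scipy.stats import spearmanr
        sess, _ = decoding_session
        ants = [0.0, 1.0, 2.0, 6.0]
        sweep = sd.anticipation_sweep(sess.eeg, sess.steering.values, ants,
                                      1.5, sess.fs, mode="global")
        rs = [cv.mean_r for _, cv in sweep]
        assert spearmanr(ants, rs).statistic < 0

    def test_sweep_deterministic(self, decoding_session):
        sess, _ = decoding_session
        a = sd.anticipation_sweep(sess.eeg, sess.steering.values, [0.0], 1.5,
                                  sess.fs, mode="global")
        b = sd.anticipation_sweep(sess.eeg, sess.steering.values, [0.0], 1.5,
                                  sess.fs, mode="global")
        np.testing.assert_array_equal(a[0][1].fold_r, b[0][1].fold_r)

    def test_prediction_length_matches(self, decoding_session):
        sess, _ = decoding_session
        model, _ = sd.fit_decoder(sess.eeg, sess.steering.values, 0.0, 1.5,
                                  sess.fs, mode="global")
        pred = model.predict(sess.eeg)
        assert pred.shape[0] == sess.n_samples


class TestCombinedDecode:
    def test_missing_stream_named(self, decoding_session):
        sess, _ = decoding_session
        with pytest.raises(ValueError, match="accel"):
            sd.combined_decode({"eeg": sess.eeg, "emg": sess.emg,
                                "eog": sess.eog}, sess.steering.values)

    def test_unreversed_equals_plain_decoder(self, decoding_session):
        sess, _ = decoding_session
        X = np.hstack([sess.eeg, sess.emg, sess.accel, sess.eog])
        cv_a = sd.combined_decode({"eeg": sess.eeg, "emg": sess.emg,
                                   "accel": sess.accel, "eog": sess.eog},
                                  sess.steering.values, 0.3, 1.5, sess.fs,
                                  mode="global")
        _, cv_b = sd.fit_decoder(X, sess.steering.values, 0.3, 1.5, sess.fs,
                                 mode="global")
        np.testing.assert_allclose(cv_a.fold_r, cv_b.fold_r, atol=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(a=st.floats(0, 12), size=st.floats(0.1, 3))
def test_anticipation_window_arithmetic_property(a, size):
    w = anticipation_to_window(a, size)
    assert w.tmax_s == pytest.approx(-a)
    assert w.tmin_s == pytest.approx(-(a + size))
    lw = latency_to_lags(w)
    assert lw.tmin_s == pytest.approx(a)
    assert lw.tmax_s == pytest.approx(a + size)


def test_frequency_band_control(decoding_session):
    """With ground-truth kernels band-limited below 3 Hz, decoding from
    0.1-3 Hz EEG matches decoding from 0.1-24 Hz EEG, while 3-24 Hz EEG
    carries no decodable signal."""
    from steerdecode.preprocess import BandSpec, bandpass_zero_phase
    sess, _ = decoding_session
    fs = sess.fs

    def decode(eeg):
        _, cv = sd.fit_decoder(eeg, sess.steering.values, 0.0, 1.5, fs,
                               mode="global")
        return cv.mean_r

    r_wide = decode(bandpass_zero_phase(sess.eeg, fs, BandSpec(0.1, 12.0, 4)))
    r_low = decode(bandpass_zero_phase(sess.eeg, fs, BandSpec(0.1, 3.0, 4)))
    r_high = decode(bandpass_zero_phase(sess.eeg, fs, BandSpec(3.0, 12.0, 4)))
    assert abs(r_wide - r_low) < 0.05
    assert r_high < 0.2 and r_high < r_low - 0.3
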