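import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import steerdecode as sd
from steerdecode.preprocess import (BandSpec, average_reference,
                                    bandpass_zero_phase, emg_envelope,
                                    flag_noisy_channels, preprocess_session,
                                    resample_to, zscore_columns)


class TestBandpass:
    def test_symmetric_pulse_stays_symmetric(self):
        # long signal: the 0.1 Hz high-pass has a tail of tens of seconds
        fs, T = 500, 60001
        x = np.zeros(T)
        x[T // 2] = 1.0
        y = bandpass_zero_phase(x, fs, BandSpec(0.1, 24.0, 4))
        asym = np.abs(y - y[::-1]).max()
        assert asym < 1e-6 * np.abs(y).max()

    def test_stopband_and_passband_gain(self):
        fs = 500
        t = np.arange(int(60 * fs)) / fs
        band = BandSpec(0.1, 24.0, 4)
        hi = bandpass_zero_phase(np.sin(2 * np.pi * 50 * t), fs, band)
        lo = bandpass_zero_phase(np.sin(2 * np.pi * 10 * t), fs, band)
        sl = slice(10 * fs, -10 * fs)  # avoid onset/edge transients
        rms_in = np.sqrt(0.5)
        assert np.sqrt(np.mean(hi[sl] ** 2)) < rms_in / 40
        assert abs(np.sqrt(np.mean(lo[sl] ** 2)) - rms_in) < 0.05 * rms_in

    def test_zero_phase_no_lag_in_passband(self):
        fs = 500
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 5 * t)
        y = bandpass_zero_phase(x, fs, BandSpec(0.1, 24.0, 4))
        lags = np.arange(-20, 21)
        xc = [np.dot(x[20:-20], y[20 + l:len(y) - 20 + l]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_edge_at_nyquist_errors(self):
        with pytest.raises(ValueError):
            bandpass_zero_phase(np.zeros(100), 100, BandSpec(0.1, 50.0, 4))


class TestResample:
    def test_length_arithmetic(self):
        out = resample_to(np.random.default_rng(0).standard_normal(5000), 500, 100)
        assert out.shape[0] == 1000

    def test_constant_preserved(self):
        out = resample_to(np.full(5000, 3.7), 500, 100)
        np.testing.assert_allclose(out, 3.7, atol=1e-9)

    def test_sinusoid_matches_analytic_grid(self):
        fs_in, fs_out = 500, 100
        t_in = np.arange(10 * fs_in) / fs_in
        out = resample_to(np.sin(2 * np.pi * t_in), fs_in, fs_out)
        t_out = np.arange(out.size) / fs_out
        ref = np.sin(2 * np.pi * t_out)
        assert np.corrcoef(out, ref)[0, 1] > 0.999

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample_to(np.zeros(100), 100, 200)


class TestAverageReference:
    def test_row_means_zero_and_idempotent(self):
        x = np.random.default_rng(1).standard_normal((500, 7))
        y = average_reference(x)
        assert np.abs(y.mean(axis=1)).max() < 1e-12
        np.testing.assert_allclose(average_reference(y), y, atol=1e-12)

    def test_two_channel_closed_form(self):
        x = np.random.default_rng(2).standard_normal((100, 2))
        y = average_reference(x)
        np.testing.assert_allclose(y[:, 0], (x[:, 0] - x[:, 1]) / 2, atol=1e-12)
        np.testing.assert_allclose(y[:, 1], (x[:, 1] - x[:, 0]) / 2, atol=1e-12)

    def test_single_channel_errors(self):
        with pytest.raises(ValueError):
            average_reference(np.zeros((10, 1)))


class TestFlagNoisyChannels:
    def test_equal_variance_none_flagged(self):
        x = np.random.default_rng(3).standard_normal((2000, 10))
        assert not flag_noisy_channels(x).any()

    def test_single_loud_channel_flagged(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((5000, 10))
        x[:, 3] *= 10.0  # variance 100 vs mean (9 + 100)/10
        mask = flag_noisy_channels(x, factor=3.0)
        assert mask[3] and mask.sum() == 1

    def test_infinite_factor_flags_nothing(self):
        x = np.random.default_rng(5).standard_normal((100, 5))
        assert not flag_noisy_channels(x, factor=np.inf).any()


class TestEmgEnvelope:
    def test_zero_input_zero_envelope(self):
        env = emg_envelope(np.zeros(1000), 500)
        np.testing.assert_allclose(env, 0.0, atol=1e-12)
        assert env.shape == (1000,)

    def test_envelope_tracks_rms_of_stationary_noise(self):
        rng = np.random.default_rng(6)
        sigma = 2.5
        x = sigma * rng.standard_normal(20000)
        env = emg_envelope(x, 500)
        interior = env[1000:-1000]
        # band-passing 20-249 Hz keeps ~92% of white-noise power
        expected = sigma * np.sqrt((249 - 20) / 250)
        assert abs(interior.mean() - expected) < 0.1 * expected
        assert (env >= 0).all()

    def test_window_too_short_errors(self):
        with pytest.raises(ValueError):
            emg_envelope(np.zeros(100), 500, win_s=0.001)


class TestZscore:
    def test_hand_example_sample_sd(self):
        z = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_idempotent(self):
        x = np.random.default_rng(7).standard_normal((200, 4)) * 5 + 3
        z = zscore_columns(x)
        np.testing.assert_allclose(zscore_columns(z), z, atol=1e-10)
        assert np.abs(z.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_constant_column_errors(self):
        x = np.ones((50, 2))
        x[:, 0] = np.arange(50)
        with pytest.raises(ValueError, match="1"):
            zscore_columns(x)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(n=st.integers(2, 8), seed=st.integers(0, 1000))
def test_average_reference_property(n, seed):
    x = np.random.default_rng(seed).standard_normal((50, n))
    y = average_reference(x)
    assert np.abs(y.mean(axis=1)).max() < 1e-10


def test_full_chain_preserves_correlation_structure():
    """Band-pass -> downsample -> re-reference keeps the inter-channel
    correlations of an already average-referenced passband signal."""
    rng = np.random.default_rng(8)
    fs_in, fs_out = 500, 100
    T = 60 * fs_in
    latent = bandpass_zero_phase(rng.standard_normal((T, 3)), fs_in,
                                 BandSpec(1.0, 15.0, 4))
    mix = rng.standard_normal((3, 6))
    x = latent @ mix
    x = x - x.mean(axis=1, keepdims=True)  # already average-referenced
    r_in = np.corrcoef(x.T)
    y = average_reference(resample_to(
        bandpass_zero_phase(x, fs_in, BandSpec(0.1, 24.0, 4)), fs_in, fs_out))
    r_out = np.corrcoef(y.T)
    assert np.abs(r_in - r_out).max() < 0.02


def test_preprocess_session_end_to_end(small_session):
    sess, _ = small_session
    out, log = preprocess_session(sess, BandSpec(0.1, 10.0, 4), fs_out=25.0)
    assert out.preprocessed and out.fs == 25.0
    assert out.n_samples == sess.n_samples
    assert np.abs(out.eeg.mean(axis=1)).max() < 1e-10
    assert log["n_channels_out"] == out.n_channels
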