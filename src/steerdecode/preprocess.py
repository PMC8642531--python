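"""Signal conditioning for all streams.

EEG path: zero-phase band-pass (0.1-24 Hz, order-4 Butterworth applied
forward and backward), downsample to 100 Hz, average re-reference, variance
based channel rejection. EMG gets two treatments: the EEG preprocessing, and
a 20-250 Hz band-passed sliding-RMS envelope. Accelerometers are z-scored.
The steering signal passes through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session import Session, SteeringSignal

__all__ = [
    "BandSpec",
    "bandpass_zero_phase",
    "resample_to",
    "average_reference",
    "flag_noisy_channels",
    "emg_envelope",
    "zscore_columns",
    "preprocess_session",
]


@dataclass(frozen=True)
class BandSpec:
    """Band-pass specification: ``order`` is per direction (forward and
    backward), so the effective magnitude response is squared."""

    low_hz: float = 0.1
    high_hz: float = 24.0
    order: int = 4

    def validate(self, fs: float) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError("band must satisfy 0 <= low < high")
        if self.high_hz >= fs / 2:
            raise ValueError(f"band edge {self.high_hz} Hz >= Nyquist {fs / 2} Hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def bandpass_zero_phase(x: np.ndarray, fs: float, band: BandSpec = BandSpec()) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, SOS form).

    Works along the time (first) axis for 1-D or 2-D input. Order applies
    per direction, i.e. the default is "order 4 + 4".
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    band.validate(fs)
    if band.low_hz > 0:
        sos = signal.butter(band.order, [band.low_hz, band.high_hz],
                            btype="band", fs=fs, output="sos")
    else:
        sos = signal.butter(band.order, band.high_hz, btype="low", fs=fs,
                            output="sos")
    # a high-pass edge at e.g. 0.1 Hz has a settling time of seconds;
    # scipy's default padding is far too short for it
    low = band.low_hz if band.low_hz > 0 else band.high_hz
    padlen = min(x.shape[0] - 1, max(int(3 * fs / low), 3 * (2 * len(sos) + 1)))
    return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Downsample along the time axis.

    Assumes the signal is already band-limited below ``fs_out/2`` (the
    pipeline band-passes first). Integer decimation factors use plain
    sample-picking; non-integer ratios fall back to polyphase resampling.
    """
    if fs_out > fs_in:
        raise ValueError("upsampling is not supported")
    if fs_out == fs_in:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) < 1e-9:
        return x[::int(round(ratio))].copy()
    from fractions import Fraction
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=0)


def average_reference(eeg: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels from every channel."""
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 2 or eeg.shape[1] < 2:
        raise ValueError("need a (T, N>=2) EEG matrix")
    return eeg - eeg.mean(axis=1, keepdims=True)


def flag_noisy_channels(eeg: np.ndarray, factor: float = 3.0) -> np.ndarray:
    """Boolean mask of channels whose variance exceeds ``factor`` times the
    mean channel variance."""
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 2 or eeg.shape[1] < 2:
        raise ValueError("need a (T, N>=2) EEG matrix")
    v = eeg.var(axis=0)
    mean_v = v.mean()
    if mean_v == 0:
        return np.zeros(eeg.shape[1], dtype=bool)
    return v > factor * mean_v


def emg_envelope(x: np.ndarray, fs: float, band: tuple[float, float] | None = None,
                 win_s: float = 0.25) -> np.ndarray:
    """Linear EMG envelope: band-pass then centered sliding-window RMS.

    Default band is 20 Hz to min(249, fs/2 - 1) Hz (an edge exactly at
    Nyquist is ill-posed). Output has the input's length; edge windows are
    truncated.
    """
    x = np.asarray(x, dtype=float)
    if band is None:
        # 20-250 Hz at the native 500 Hz rate; for lower rates the band
        # scales down so the envelope path stays well-posed
        band = (min(20.0, fs / 4), min(249.0, fs / 2 - 1))
    win = int(round(win_s * fs))
    if win < 2:
        raise ValueError("RMS window must span at least 2 samples")
    if fs <= 2 * band[0] or band[0] >= band[1]:
        raise ValueError("sampling rate too low for the EMG band")
    bp = bandpass_zero_phase(x, fs, BandSpec(band[0], band[1], 4))
    sq = bp ** 2
    ones = np.ones(win)
    if sq.ndim == 1:
        num = np.convolve(sq, ones, mode="same")
        den = np.convolve(np.ones_like(sq), ones, mode="same")
    else:
        num = np.apply_along_axis(lambda c: np.convolve(c, ones, mode="same"), 0, sq)
        den = np.convolve(np.ones(sq.shape[0]), ones, mode="same")[:, None]
    return np.sqrt(num / den)


def zscore_columns(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Z-score each column (sample sd, n-1 denominator by default)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sd = X.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant column(s) cannot be z-scored: {bad.tolist()}")
    return (X - X.mean(axis=0)) / sd


def preprocess_session(sess: Session, band: BandSpec = BandSpec(),
                       fs_out: float = 100.0, reject_factor: float = 3.0,
                       exclude_channels: list[int] | None = None
                       ) -> tuple[Session, dict]:
    """Full conditioning chain on a session; returns (session, log).

    EEG: band-pass -> downsample -> drop excluded channels -> average
    re-reference -> variance-based rejection. EMG: EEG-style preprocessing
    (the envelope is computed separately by the CCA stage at the original
    rate, then downsampled). EOG: EEG-style band-pass + downsample.
    Accelerometers: z-scored and downsampled. Steering: resampled only.
    """
    fs = sess.fs
    if fs_out > fs:
        raise ValueError("fs_out must not exceed the session rate")

    eeg = resample_to(bandpass_zero_phase(sess.eeg, fs, band), fs, fs_out)
    keep = np.ones(eeg.shape[1], dtype=bool)
    if exclude_channels:
        keep[np.asarray(exclude_channels, dtype=int)] = False
    eeg = eeg[:, keep]
    labels = [l for l, k in zip(sess.eeg_labels, keep) if k]
    eeg = average_reference(eeg)
    noisy = flag_noisy_channels(eeg, reject_factor)
    if noisy.any():
        eeg = eeg[:, ~noisy]
        labels = [l for l, n in zip(labels, noisy) if not n]

    emg_like = resample_to(bandpass_zero_phase(sess.emg, fs, band), fs, fs_out)
    emg_env = resample_to(emg_envelope(sess.emg, fs), fs, fs_out)
    eog = resample_to(bandpass_zero_phase(sess.eog, fs, band), fs, fs_out)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        accel = resample_to(zscore_columns(sess.accel), fs, fs_out)
    steer = resample_to(sess.steering.values, fs, fs_out)

    T = min(a.shape[0] for a in (eeg, emg_like, eog, accel, emg_env))
    T = min(T, steer.shape[0])
    out = Session(eeg=eeg[:T], emg=emg_like[:T], accel=accel[:T], eog=eog[:T],
                  steering=SteeringSignal(steer[:T], fs_out), fs=fs_out,
                  eeg_labels=labels, preprocessed=True,
                  meta={**sess.meta, "emg_env": emg_env[:T]})
    log = {
        "band": [band.low_hz, band.high_hz], "order": band.order,
        "fs_in": fs, "fs_out": fs_out,
        "excluded": list(exclude_channels or []),
        "rejected": np.flatnonzero(noisy).tolist(),
        "n_channels_out": out.n_channels,
    }
    return out, log
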