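"""Aligned multistream recording container.

A :class:`Session` holds every stream of one simulated driving recording —
multichannel EEG, bipolar EMG, accelerometers, bipolar EOG and the univariate
steering-wheel angle — aligned to a common clock. All analysis stages consume
and return this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SteeringSignal", "Session"]


@dataclass
class SteeringSignal:
    """Continuous steering-wheel angle.

    Parameters
    ----------
    values : ndarray, shape (T,)
        Steering angle in arbitrary units (approximately zero-mean).
    fs : float
        Sampling rate in Hz.
    """

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("steering must be univariate (1-D)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("steering contains non-finite values")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass
class Session:
    """Temporally aligned recording streams.

    All stream arrays share the first (time) axis; ``fs`` is the common
    sampling rate. Channel counts follow the recording montage being
    emulated: 4 bipolar EMG channels, 12 accelerometer axes (two 6-axis
    inertial units), 3 bipolar EOG channels.
    """

    eeg: np.ndarray               # (T, N)
    emg: np.ndarray               # (T, 4)
    accel: np.ndarray             # (T, 12)
    eog: np.ndarray               # (T, 3)
    steering: SteeringSignal
    fs: float
    eeg_labels: list[str] = field(default_factory=list)
    preprocessed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.eog = np.atleast_2d(np.asarray(self.eog, dtype=float))
        T = self.eeg.shape[0]
        for name in ("emg", "accel", "eog"):
            arr = getattr(self, name)
            if arr.shape[0] != T:
                raise ValueError(f"{name} has {arr.shape[0]} samples, EEG has {T}")
        if self.steering.n_samples != T:
            raise ValueError("steering not aligned with EEG")
        if self.eeg.shape[1] < 2:
            raise ValueError("need at least 2 EEG channels")
        for name in ("eeg", "emg", "accel", "eog"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains NaN/inf")
        if not self.eeg_labels:
            self.eeg_labels = [f"E{i + 1}" for i in range(self.eeg.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[1]

    def copy_with(self, **kwargs) -> "Session":
        """Return a shallow-copied session with fields replaced."""
        return replace(self, **kwargs)
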