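"""Session persistence: HDF5 container, steering CSV, optional EDF reader."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .session import Session, SteeringSignal

__all__ = ["save_session", "load_session", "save_steering_csv",
           "load_steering_csv", "load_edf"]

_STREAMS = ("eeg", "emg", "accel", "eog")


def save_session(sess: Session, path: str) -> str:
    """Write a session to an HDF5 container (one dataset per stream,
    fs/labels/flags as attributes). Array-valued ``meta`` entries become
    datasets under ``meta/``; scalars become attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        for name in _STREAMS:
            f.create_dataset(name, data=getattr(sess, name))
        f.create_dataset("steering", data=sess.steering.values)
        f.attrs["fs"] = sess.fs
        f.attrs["steering_fs"] = sess.steering.fs
        f.attrs["preprocessed"] = sess.preprocessed
        f.attrs["eeg_labels"] = [l.encode() for l in sess.eeg_labels]
        grp = f.create_group("meta")
        for k, v in sess.meta.items():
            if isinstance(v, np.ndarray):
                grp.create_dataset(k, data=v)
            else:
                grp.attrs[k] = v
    return path


def load_session(path: str) -> Session:
    import h5py

    with h5py.File(path, "r") as f:
        if "fs" not in f.attrs:
            raise ValueError("container missing required attribute 'fs'")
        for name in _STREAMS + ("steering",):
            if name not in f:
                raise ValueError(f"container missing required stream {name!r}")
        fs = float(f.attrs["fs"])
        streams = {name: f[name][()] for name in _STREAMS}
        steer = SteeringSignal(f["steering"][()],
                               float(f.attrs.get("steering_fs", fs)))
        labels = [l.decode() if isinstance(l, bytes) else str(l)
                  for l in f.attrs.get("eeg_labels", [])]
        meta = {}
        if "meta" in f:
            meta.update({k: v for k, v in f["meta"].attrs.items()})
            meta.update({k: f["meta"][k][()] for k in f["meta"].keys()})
        return Session(steering=steer, fs=fs, eeg_labels=labels,
                       preprocessed=bool(f.attrs.get("preprocessed", False)),
                       meta=meta, **streams)


def save_steering_csv(steering: SteeringSignal, path: str) -> str:
    t = np.arange(steering.n_samples) / steering.fs
    pd.DataFrame({"time_s": t, "angle": steering.values}).to_csv(path, index=False)
    return path


def load_steering_csv(path: str) -> SteeringSignal:
    df = pd.read_csv(path)
    if not {"time_s", "angle"} <= set(df.columns):
        raise ValueError("steering CSV must have columns time_s, angle")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError("steering CSV time axis must be strictly increasing")
    fs = 1.0 / np.median(dt)
    return SteeringSignal(df["angle"].to_numpy(dtype=float), fs)


def load_edf(path: str):
    """Read a multichannel EDF/BDF recording (EEG matrix, labels, fs).

    Optional reader for real recordings; requires :mod:`mne`.
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("EDF reading requires the 'mne' package") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data().T, list(raw.ch_names), float(raw.info["sfreq"])
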