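"""Reversible CCA-based removal of nuisance-correlated EEG components.

Canonical correlation analysis between the EEG (T x J2) and a *noise
matrix* (T x J1) built from the measured nuisance recordings — EMG
(EEG-preprocessed and envelope), accelerometers, EOG — padded with white
noise columns so that J1 = J2. The padding makes the EEG-side transform W2
square, hence the rotation into canonical space is exactly invertible:
zeroing no components and back-projecting returns the EEG unchanged, and
removing the k most noise-correlated components is a well-defined, purely
subtractive operation. Without padding (J1 < J2) the back-projection would
compress the EEG and alter it even for unrelated noise.

Only instantaneous (zero-lag) correlations are targeted: no lagged copies
of the noise enter the matrix. Anticipatory brain signals, which lead the
action rather than co-occurring with the nuisances, survive the removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseMatrix",
    "CCADecomposition",
    "build_noise_matrix",
    "fit_cca",
    "select_noise_components",
    "remove_components",
    "denoise_eeg",
]


@dataclass
class NoiseMatrix:
    values: np.ndarray            # (T, J1)
    column_labels: list[str]
    seed: int | None = None

    @property
    def n_real(self) -> int:
        return sum(1 for l in self.column_labels if l != "white_noise")


def build_noise_matrix(emg_eeg_like: np.ndarray, emg_env: np.ndarray,
                       accel: np.ndarray, eog: np.ndarray, n_target: int,
                       seed: int | None = None) -> NoiseMatrix:
    """Concatenate nuisance streams and pad with white noise to ``n_target``
    columns.

    Column order: EMG (EEG-preprocessed), EMG envelopes, accelerometers,
    EOG, then i.i.d. standard-normal padding columns drawn from ``seed``.
    """
    blocks = [np.atleast_2d(np.asarray(a, dtype=float)) for a in
              (emg_eeg_like, emg_env, accel, eog)]
    T = blocks[0].shape[0]
    for b in blocks:
        if b.shape[0] != T:
            raise ValueError("all nuisance streams must have equal length")
    labels: list[str] = []
    for name, b in zip(("emg", "emg_env", "accel", "eog"), blocks):
        labels += [f"{name}_{j}" for j in range(b.shape[1])]
    n_real = len(labels)
    if n_target < n_real:
        raise ValueError(f"n_target={n_target} < {n_real} real noise columns; "
                         "padding cannot be negative")
    n_pad = n_target - n_real
    rng = np.random.default_rng(seed)
    pad = rng.standard_normal((T, n_pad))
    values = np.hstack(blocks + [pad]) if n_pad else np.hstack(blocks)
    labels += ["white_noise"] * n_pad
    return NoiseMatrix(values=values, column_labels=labels, seed=seed)


@dataclass
class CCADecomposition:
    """Full CCA of noise (X) against EEG (Y).

    ``W1`` (J1 x J0) and ``W2`` (J2 x J0) map each block to unit-variance,
    mutually uncorrelated canonical variates; ``rho`` holds the J0 canonical
    correlations in non-increasing order. ``x_mean``/``y_mean`` are the
    column means removed before fitting (added back on back-projection).
    """

    W1: np.ndarray
    W2: np.ndarray
    rho: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    rank_x: int
    rank_y: int


def _whiten(Z: np.ndarray, rcond: float = 1e-10):
    """Economy SVD with relative singular-value cutoff; returns (Q, K, rank)
    with Q = Z @ K having orthonormal columns."""
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > rcond * s[0])) if s.size else 0
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    K = Vt.T / s
    return U, K, rank


def fit_cca(X: np.ndarray, Y: np.ndarray, rcond: float = 1e-10) -> CCADecomposition:
    """CCA via SVD whitening of both blocks and SVD of the cross product.

    Deterministic sign convention: the largest-magnitude element of each W2
    column is positive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    T = X.shape[0]
    if Y.shape[0] != T:
        raise ValueError("X and Y must have the same number of samples")
    if T <= max(X.shape[1], Y.shape[1]):
        raise ValueError("need more samples than columns in either block")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    Ux, Kx, rx = _whiten(Xc, rcond)
    Uy, Ky, ry = _whiten(Yc, rcond)
    A, rho, Bt = np.linalg.svd(Ux.T @ Uy, full_matrices=False)
    scale = np.sqrt(T - 1)
    W1 = Kx @ A * scale
    W2 = Ky @ Bt.T * scale
    # sign convention on the EEG-side transform
    for j in range(W2.shape[1]):
        if W2[np.argmax(np.abs(W2[:, j])), j] < 0:
            W2[:, j] = -W2[:, j]
            W1[:, j] = -W1[:, j]
    return CCADecomposition(W1=W1, W2=W2, rho=np.clip(rho, 0.0, 1.0),
                            x_mean=x_mean, y_mean=y_mean, rank_x=rx, rank_y=ry)


def select_noise_components(rho: np.ndarray, percentile: float = 90.0) -> np.ndarray:
    """Mask of components whose canonical correlation strictly exceeds the
    given percentile (linear interpolation) of all canonical correlations.

    ``rho`` is non-increasing, so the mask is always a prefix of the
    component list.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.size == 0:
        raise ValueError("empty canonical-correlation vector")
    if np.any(np.diff(rho) > 1e-12):
        raise ValueError("rho must be non-increasing")
    thresh = np.percentile(rho, percentile)
    return rho > thresh


def remove_components(Y: np.ndarray, decomp: CCADecomposition,
                      mask: np.ndarray) -> np.ndarray:
    """Zero the masked canonical components and back-project to EEG space.

    Requires a square, invertible W2 (guaranteed by white-noise padding of
    the noise matrix); otherwise the mapping would not be reversible and
    even an empty mask would alter the EEG.
    """
    W2 = decomp.W2
    if W2.shape[0] != W2.shape[1]:
        raise ValueError("W2 is not square; pad the noise matrix so J1 = J2 "
                         "to guarantee a reversible mapping")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (W2.shape[1],):
        raise ValueError("mask length must equal the number of components")
    Yc = np.asarray(Y, dtype=float) - decomp.y_mean
    Z = Yc @ W2
    Z[:, mask] = 0.0
    W2_inv = np.linalg.inv(W2)
    return Z @ W2_inv + decomp.y_mean


def denoise_eeg(eeg: np.ndarray, emg_eeg_like: np.ndarray, emg_env: np.ndarray,
                accel: np.ndarray, eog: np.ndarray, percentile: float = 90.0,
                seed: int | None = None):
    """Convenience wrapper: build the padded noise matrix, fit CCA, remove
    the most noise-correlated components, back-project.

    Returns ``(eeg_den, decomposition, mask)``.
    """
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    noise = build_noise_matrix(emg_eeg_like, emg_env, accel, eog,
                               n_target=eeg.shape[1], seed=seed)
    decomp = fit_cca(noise.values, eeg)
    mask = select_noise_components(decomp.rho, percentile)
    return remove_components(eeg, decomp, mask), decomp, mask
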