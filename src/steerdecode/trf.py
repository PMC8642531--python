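"""Lagged linear regression (LLR): temporal response functions by ridge.

Forward ("encoding") models map the steering signal to each EEG channel
over a signed lag window; backward ("decoding") models reconstruct the
steering from a window of preceding EEG. Both are ridge regressions on a
time-lag expansion of the predictor, cross-validated over contiguous folds
with an exhaustive log-spaced search for the regularisation parameter.

Canonical lag convention
------------------------
``y(t) = sum_tau w(tau) x(t - tau)`` with ``tau`` in ``[tmin, tmax]``
samples of signed lag. Negative ``tau`` means the predictor is taken from
the *future* of ``y``'s clock. For the forward model (x = steering,
y = EEG) negative lags therefore capture EEG that precedes the action. The
decoder's "anticipation" axis is expressed in steering-EEG latency (EEG
time minus steering time, negative = EEG earlier) and converted to
canonical predictor lags by :func:`latency_to_lags` — a pure sign flip.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LagWindow",
    "TRFModel",
    "CVResult",
    "DecoderConfig",
    "lag_design",
    "ridge_solve",
    "cross_validated_fit",
    "fit_encoder",
    "anticipation_to_window",
    "latency_to_lags",
    "fit_decoder",
    "anticipation_sweep",
    "combined_decode",
    "pearson_r",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_ANTICIPATIONS",
]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 9, 13))
DEFAULT_ANTICIPATIONS = (0.0, 0.3, 0.6, 0.9, 1.2, 1.5, 1.8, 2.1, 2.4, 2.7,
                         3.0, 6.0, 12.0)


@dataclass(frozen=True)
class LagWindow:
    """Signed lag window in seconds; must be representable in samples."""

    tmin_s: float
    tmax_s: float

    def __post_init__(self):
        if self.tmin_s > self.tmax_s:
            raise ValueError("tmin_s must be <= tmax_s")

    def lags(self, fs: float) -> np.ndarray:
        """Integer sample lags, tmin to tmax inclusive."""
        return np.arange(int(round(self.tmin_s * fs)),
                         int(round(self.tmax_s * fs)) + 1)

    def n_lags(self, fs: float) -> int:
        return self.lags(fs).size


@dataclass
class TRFModel:
    direction: str                 # "forward" | "backward"
    window: LagWindow              # canonical lag convention
    weights: np.ndarray            # (L, C, K): lags x inputs x outputs
    bias: np.ndarray               # (K,)
    lam: float
    fs: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        D = lag_design(x, self.window, self.fs)
        L, C, K = self.weights.shape
        w = self.weights.transpose(1, 0, 2).reshape(C * L, K)
        return D @ w + self.bias


@dataclass
class CVResult:
    fold_r: np.ndarray             # per-fold Pearson r (mean across outputs)
    mean_r: float
    lambda_grid: np.ndarray
    lambda_selected: float
    fold_boundaries: list[tuple[int, int]]
    fold_lambdas: np.ndarray = field(default=None)

    def __post_init__(self):
        self.fold_r = np.asarray(self.fold_r, dtype=float)
        self.mean_r = float(np.mean(self.fold_r))


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    out = np.zeros_like(x)
    if lag == 0:
        out[:] = x
    elif lag > 0:
        out[lag:] = x[:-lag]
    else:
        out[:lag] = x[-lag:]
    return out


def lag_design(x: np.ndarray, window: LagWindow, fs: float) -> np.ndarray:
    """Time-lag expansion: column (c, tau) holds channel c delayed by tau.

    Columns are ordered channel-major, lag-minor: for channel c and the
    j-th lag of L, the column index is ``c * L + j``. Edges are
    zero-padded ("same" alignment).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    T, C = x.shape
    lags = window.lags(fs)
    L = lags.size
    if L > T:
        raise ValueError("lag window longer than the signal")
    D = np.empty((T, C * L))
    for c in range(C):
        for j, lag in enumerate(lags):
            D[:, c * L + j] = _shift(x[:, c], int(lag))
    return D


def _difference_penalty(P: int) -> np.ndarray:
    """First-difference (smoothing) penalty M = D1' D1 + small identity."""
    D1 = np.diff(np.eye(P), axis=0)
    return D1.T @ D1 + 1e-8 * np.eye(P)


def ridge_solve(D: np.ndarray, y: np.ndarray, lam: float,
                penalty: str = "identity") -> tuple[np.ndarray, np.ndarray]:
    """Ridge solution ``w = (D'D + lam*M)^-1 D'y`` with internal centering.

    ``y`` may be (T,) or (T, K). The bias restores the removed means. At
    ``lam = 0`` a singular system falls back to the pseudo-inverse with a
    warning.
    """
    D = np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    mu_d = D.mean(axis=0)
    mu_y = y.mean(axis=0)
    Dc = D - mu_d
    yc = y - mu_y
    G = Dc.T @ Dc
    b = Dc.T @ yc
    P = G.shape[0]
    M = np.eye(P) if penalty == "identity" else _difference_penalty(P)
    A = G + lam * M
    try:
        if lam == 0 and np.linalg.matrix_rank(G) < P:
            raise np.linalg.LinAlgError
        w = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        warnings.warn("singular normal equations at lambda=0; using pseudo-inverse")
        w = np.linalg.pinv(A) @ b
    bias = mu_y - mu_d @ w
    if squeeze:
        return w[:, 0], bias[0]
    return w, bias


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; errors on zero-variance input."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb))


# ---------------------------------------------------------------------------
# cross-validation machinery (fold-wise Gram caching)

def fold_slices(T: int, n_folds: int) -> list[tuple[int, int]]:
    """Contiguous, disjoint fold boundaries covering [0, T); sizes differ by
    at most one sample."""
    if n_folds < 3:
        raise ValueError("need at least 3 folds")
    if T < n_folds:
        raise ValueError("session shorter than the number of folds")
    edges = np.linspace(0, T, n_folds + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_folds)]


class _FoldGrams:
    """Per-fold sufficient statistics so any union of folds can be solved
    without touching the raw design again."""

    def __init__(self, D: np.ndarray, y: np.ndarray, bounds):
        self.bounds = bounds
        self.A = []   # D_f' D_f
        self.b = []   # D_f' y_f
        self.sx = []  # column sums of D_f
        self.sy = []
        self.n = []
        self.D = D
        self.y = y
        for lo, hi in bounds:
            Df, yf = D[lo:hi], y[lo:hi]
            self.A.append(Df.T @ Df)
            self.b.append(Df.T @ yf)
            self.sx.append(Df.sum(axis=0))
            self.sy.append(yf.sum(axis=0))
            self.n.append(hi - lo)

    def train_stats(self, fold_ids):
        n = sum(self.n[i] for i in fold_ids)
        sx = sum(self.sx[i] for i in fold_ids)
        sy = sum(self.sy[i] for i in fold_ids)
        A = sum(self.A[i] for i in fold_ids)
        b = sum(self.b[i] for i in fold_ids)
        mu_x, mu_y = sx / n, sy / n
        G = A - n * np.outer(mu_x, mu_x)
        C = b - n * np.outer(mu_x, mu_y)
        return G, C, mu_x, mu_y, n


class _TrainSolver:
    """Eigendecomposition of one training set's (standardized) Gram; solves
    the ridge system for any lambda at negligible marginal cost."""

    def __init__(self, grams: _FoldGrams, fold_ids, standardize: bool):
        G, C, self.mu_x, self.mu_y, n = grams.train_stats(fold_ids)
        if standardize:
            var = np.clip(np.diag(G) / max(n - 1, 1), 1e-24, None)
            self.sigma = np.sqrt(var)
        else:
            self.sigma = np.ones(G.shape[0])
        Gs = G / np.outer(self.sigma, self.sigma)
        self.Cs = C / self.sigma[:, None]
        evals, evecs = np.linalg.eigh(Gs)
        self.evals = np.clip(evals, 0.0, None)
        self.evecs = evecs
        self._VtC = evecs.T @ self.Cs

    def solve(self, lam: float):
        denom = self.evals + lam
        if lam == 0:
            tiny = denom <= 1e-12 * max(self.evals.max(), 1.0)
            denom = np.where(tiny, np.inf, denom)
        ws = self.evecs @ (self._VtC / denom[:, None])
        w = ws / self.sigma[:, None]
        bias = self.mu_y - self.mu_x @ w
        return w, bias


def _score_fold(grams: _FoldGrams, fold: int, w, bias) -> float:
    lo, hi = grams.bounds[fold]
    pred = grams.D[lo:hi] @ w + bias
    actual = grams.y[lo:hi]
    rs = []
    for k in range(actual.shape[1]):
        if pred[:, k].std() == 0 or actual[:, k].std() == 0:
            rs.append(0.0)
        else:
            rs.append(pearson_r(pred[:, k], actual[:, k]))
    return float(np.mean(rs))


def cross_validated_fit(x: np.ndarray, y: np.ndarray, window: LagWindow,
                        fs: float, lambda_grid=DEFAULT_LAMBDA_GRID,
                        n_folds: int = 10, mode: str = "nested",
                        standardize: bool = True,
                        direction: str = "forward") -> tuple[TRFModel, CVResult]:
    """Cross-validated lagged ridge fit.

    Folds are contiguous time blocks (steering is strongly autocorrelated;
    random-sample folds would leak across the train/test boundary).

    ``mode="nested"`` (default): for each outer fold, lambda is chosen by
    leave-one-training-fold-out validation on the training folds only, the
    model is refit on all training data, and r is computed on the held-out
    fold. The final reported model is refit on all data at the modal
    selected lambda. ``mode="global"``: one lambda maximising the plain
    K-fold mean r (simpler, slightly optimistic protocol).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    D = lag_design(x, window, fs)
    T = D.shape[0]
    bounds = fold_slices(T, n_folds)
    grams = _FoldGrams(D, y, bounds)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    all_folds = list(range(n_folds))

    fold_r = np.empty(n_folds)
    fold_lams = np.empty(n_folds)

    if mode == "global":
        scores = np.zeros(lambda_grid.size)
        solvers = []
        for k in all_folds:
            train = [i for i in all_folds if i != k]
            solvers.append(_TrainSolver(grams, train, standardize))
        for li, lam in enumerate(lambda_grid):
            scores[li] = np.mean([_score_fold(grams, k, *solvers[k].solve(lam))
                                  for k in all_folds])
        best = lambda_grid[int(np.argmax(scores))]
        for k in all_folds:
            fold_r[k] = _score_fold(grams, k, *solvers[k].solve(best))
            fold_lams[k] = best
        final_lam = float(best)
    elif mode == "nested":
        for k in all_folds:
            train = [i for i in all_folds if i != k]
            inner_scores = np.zeros(lambda_grid.size)
            for j in train:
                inner_train = [i for i in train if i != j]
                solver = _TrainSolver(grams, inner_train, standardize)
                for li, lam in enumerate(lambda_grid):
                    inner_scores[li] += _score_fold(grams, j, *solver.solve(lam))
            lam_k = lambda_grid[int(np.argmax(inner_scores))]
            solver = _TrainSolver(grams, train, standardize)
            fold_r[k] = _score_fold(grams, k, *solver.solve(lam_k))
            fold_lams[k] = lam_k
        counts = Counter(fold_lams.tolist())
        top = max(counts.values())
        final_lam = float(min(l for l, c in counts.items() if c == top))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    solver = _TrainSolver(grams, all_folds, standardize)
    w, bias = solver.solve(final_lam)
    C = x.shape[1] if x.ndim == 2 else 1
    L = window.n_lags(fs)
    weights = w.reshape(C, L, y.shape[1]).transpose(1, 0, 2)
    model = TRFModel(direction=direction, window=window, weights=weights,
                     bias=bias, lam=final_lam, fs=fs)
    cv = CVResult(fold_r=fold_r, mean_r=0.0, lambda_grid=lambda_grid,
                  lambda_selected=final_lam, fold_boundaries=bounds,
                  fold_lambdas=fold_lams)
    return model, cv


# ---------------------------------------------------------------------------
# encoding / decoding front-ends

def fit_encoder(steering: np.ndarray, eeg: np.ndarray,
                window: LagWindow = LagWindow(-1.5, 0.5), fs: float = 100.0,
                **kwargs) -> tuple[TRFModel, CVResult]:
    """Forward model: steering -> EEG, all channels jointly (shared lambda).

    Under the canonical convention negative lags capture EEG that precedes
    the steering action; ``model.weights`` has shape (L, 1, N) and
    ``weights[j, 0, n]`` is channel n's TRF weight at the j-th lag of
    ``window.lags(fs)``.
    """
    return cross_validated_fit(steering, eeg, window, fs,
                               direction="forward", **kwargs)


def anticipation_to_window(anticipation_s: float, size_s: float = 1.5) -> LagWindow:
    """Decoder latency window ``[-(a + size), -a]`` in steering-EEG latency
    (negative = EEG precedes the steering sample being predicted)."""
    if anticipation_s < 0:
        raise ValueError("anticipation must be >= 0")
    if size_s <= 0:
        raise ValueError("window size must be > 0")
    return LagWindow(-(anticipation_s + size_s), -anticipation_s)


def latency_to_lags(window: LagWindow) -> LagWindow:
    """Convert a steering-EEG latency window to canonical predictor lags.

    A latency of -a s (EEG a seconds before the steering sample) is a
    predictor lag of +a s in ``y(t) = sum w(tau) x(t - tau)``; the window
    flips sign and swaps its ends.
    """
    return LagWindow(-window.tmax_s, -window.tmin_s)


@dataclass(frozen=True)
class DecoderConfig:
    """Everything needed to rerun one decoding fit (used verbatim by the
    shuffled-fold null)."""

    anticipation_s: float = 0.0
    size_s: float = 1.5
    fs: float = 100.0
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    n_folds: int = 10
    mode: str = "nested"
    standardize: bool = True


def fit_decoder(eeg: np.ndarray, steering: np.ndarray, anticipation_s: float = 0.0,
                size_s: float = 1.5, fs: float = 100.0,
                **kwargs) -> tuple[TRFModel, CVResult]:
    """Backward model: EEG -> steering, using only EEG in
    ``[t - (a + size), t - a]`` to predict the steering at time t."""
    latency = anticipation_to_window(anticipation_s, size_s)
    window = latency_to_lags(latency)
    return cross_validated_fit(eeg, steering, window, fs,
                               direction="backward", **kwargs)


def run_decoder(eeg: np.ndarray, steering: np.ndarray,
                cfg: DecoderConfig) -> CVResult:
    _, cv = fit_decoder(eeg, steering, cfg.anticipation_s, cfg.size_s, cfg.fs,
                        lambda_grid=cfg.lambda_grid, n_folds=cfg.n_folds,
                        mode=cfg.mode, standardize=cfg.standardize)
    return cv


def anticipation_sweep(eeg: np.ndarray, steering: np.ndarray,
                       anticipations=DEFAULT_ANTICIPATIONS, size_s: float = 1.5,
                       fs: float = 100.0, **kwargs) -> list[tuple[float, CVResult]]:
    """Decode at each anticipation; returns [(anticipation_s, CVResult)]."""
    anticipations = list(anticipations)
    if not anticipations:
        raise ValueError("empty anticipation list")
    out = []
    for a in anticipations:
        _, cv = fit_decoder(eeg, steering, a, size_s, fs, **kwargs)
        out.append((a, cv))
    return out


def combined_decode(streams: dict, steering: np.ndarray, anticipation_s: float = 0.0,
                    size_s: float = 1.5, fs: float = 100.0,
                    reverse_eeg: bool = False, **kwargs) -> CVResult:
    """Decode from EEG + nuisance streams concatenated channel-wise.

    With ``reverse_eeg`` the EEG block is time-reversed before lagging
    (the nuisance streams are untouched): any genuine EEG contribution to
    the decoding is destroyed while the nuisance contribution survives.
    """
    for name in ("eeg", "emg", "accel", "eog"):
        if name not in streams or streams[name] is None:
            raise ValueError(f"missing stream: {name!r}")
    eeg = np.atleast_2d(np.asarray(streams["eeg"], dtype=float))
    if reverse_eeg:
        eeg = eeg[::-1]
    X = np.hstack([eeg] + [np.atleast_2d(np.asarray(streams[k], dtype=float))
                           for k in ("emg", "accel", "eog")])
    _, cv = fit_decoder(X, steering, anticipation_s, size_s, fs, **kwargs)
    return cv
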