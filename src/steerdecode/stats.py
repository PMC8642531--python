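"""Null baselines and the group-level statistical battery.

The decoding null is a *shuffled-fold* baseline: the cross-validated
decoding is rerun after randomly permuting the EEG fold identities, so each
steering fold is paired with a random EEG fold. Repeating this (100 times
by default) yields the distribution of decoding correlations expected from
the signals' autocorrelation alone; its 95th percentile is the chance
baseline a genuine decoder must exceed.

Group analyses: Wilcoxon signed-rank on TRF weights with BH-FDR across
latencies, repeated-measures ANOVA (Greenhouse-Geisser corrected when
Mauchly's sphericity test fails, partial eta squared effect sizes), and
add-one permutation p-values against the shuffled-fold null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .trf import DecoderConfig, fold_slices, run_decoder

__all__ = [
    "NullDistribution",
    "AnovaResult",
    "shuffled_fold_null",
    "baseline_threshold",
    "fdr_bh",
    "encoder_group_significance",
    "rm_anova",
    "permutation_pvalue",
]


@dataclass
class NullDistribution:
    values: np.ndarray
    n_iter: int
    seed: int | None = None
    percentile_baselines: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_iter:
            raise ValueError("values length must equal n_iter")


def shuffle_eeg_folds(eeg: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Reassemble the EEG with its fold blocks in uniformly random order.

    The session is truncated to a multiple of the fold count so every block
    has the same length and blocks are interchangeable sample-for-sample.
    """
    T = eeg.shape[0] - eeg.shape[0] % n_folds
    eeg = eeg[:T]
    perm = rng.permutation(n_folds)
    blocks = [eeg[lo:hi] for lo, hi in fold_slices(T, n_folds)]
    return np.vstack([blocks[p] for p in perm])


def shuffled_fold_null(eeg: np.ndarray, steering: np.ndarray,
                       decoder_config: DecoderConfig, n_iter: int = 100,
                       seed: int | None = None,
                       percentiles=(50, 95, 99)) -> NullDistribution:
    """Decoding null by mispairing steering and EEG cross-validation folds."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    steering = np.asarray(steering, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    n_folds = decoder_config.n_folds
    T = eeg.shape[0] - eeg.shape[0] % n_folds
    values = np.empty(n_iter)
    for i in range(n_iter):
        eeg_perm = shuffle_eeg_folds(eeg, n_folds, rng)
        cv = run_decoder(eeg_perm, steering[:T], decoder_config)
        values[i] = cv.mean_r
    null = NullDistribution(values=values, n_iter=n_iter, seed=seed)
    null.percentile_baselines = {p: baseline_threshold(null, p)
                                 for p in percentiles}
    return null


def baseline_threshold(null: NullDistribution, percentile: float = 95.0) -> float:
    """Linear-interpolated percentile of the null decoding correlations."""
    if null.values.size == 0:
        raise ValueError("empty null distribution")
    return float(np.percentile(null.values, percentile))


def fdr_bh(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def encoder_group_significance(trf_stack: np.ndarray, alpha: float = 0.05
                               ) -> np.ndarray:
    """Group-level TRF weight significance, per (lag, channel).

    Wilcoxon signed-rank across subjects against zero at every lag/channel,
    then BH-FDR across latencies *within* each channel. Uses the exact null
    distribution for fewer than 10 subjects and the normal approximation
    with continuity correction otherwise.
    """
    trf_stack = np.asarray(trf_stack, dtype=float)
    if trf_stack.ndim != 3:
        raise ValueError("expected a (subjects, lags, channels) stack")
    S, L, N = trf_stack.shape
    if S < 2:
        raise ValueError("need at least 2 subjects")
    method = "exact" if S < 10 else "approx"
    pvals = np.ones((L, N))
    for n in range(N):
        for l in range(L):
            x = trf_stack[:, l, n]
            if np.allclose(x, 0):
                continue
            res = sps.wilcoxon(x, zero_method="wilcox", correction=True,
                               method=method)
            pvals[l, n] = res.pvalue
    mask = np.zeros((L, N), dtype=bool)
    for n in range(N):
        mask[:, n] = fdr_bh(pvals[:, n], q=alpha)
    return mask


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_effect: float
    df_error: float
    p: float
    eta_p2: float
    gg_epsilon: float | None = None
    mauchly_p: float | None = None
    gg_applied: bool = False


def _long_format(data: np.ndarray, factors: list[str]) -> pd.DataFrame:
    rows = []
    if data.ndim == 2:
        S, A = data.shape
        for s in range(S):
            for a in range(A):
                rows.append({"subject": s, factors[0]: a, "y": data[s, a]})
    else:
        S, A, B = data.shape
        for s in range(S):
            for a in range(A):
                for b in range(B):
                    rows.append({"subject": s, factors[0]: a, factors[1]: b,
                                 "y": data[s, a, b]})
    return pd.DataFrame(rows)


def rm_anova(data: np.ndarray, factor_names: list[str] | None = None
             ) -> list[AnovaResult]:
    """Repeated-measures ANOVA on a (subjects x levels [x levels2]) array.

    One-way: sphericity is checked with Mauchly's test and the
    Greenhouse-Geisser correction applied when it fails (p < .05, >= 3
    levels). Two-way: both main effects and the interaction are reported
    with the same correction policy per effect. Effect size is partial eta
    squared.
    """
    import pingouin as pg

    data = np.asarray(data, dtype=float)
    if data.ndim not in (2, 3):
        raise ValueError("data must be (subjects, levels) or (subjects, l1, l2)")
    if np.any(~np.isfinite(data)):
        raise ValueError("missing cells: the design must be complete")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if factor_names is None:
        factor_names = ["A", "B"][:data.ndim - 1]
    df = _long_format(data, factor_names)

    results = []
    if data.ndim == 2:
        n_levels = data.shape[1]
        aov = pg.rm_anova(data=df, dv="y", within=factor_names[0],
                          subject="subject", detailed=True, effsize="np2",
                          correction=(n_levels >= 3))
        row = aov.loc[aov["Source"] == factor_names[0]].iloc[0]
        mauchly_p = None
        gg_eps = None
        gg_applied = False
        p = float(row["p_unc"])
        if n_levels >= 3:
            mauchly_p = float(row["p_spher"])
            gg_eps = float(row["eps"])
            if mauchly_p < 0.05 and np.isfinite(row["p_GG_corr"]):
                p = float(row["p_GG_corr"])
                gg_applied = True
        results.append(AnovaResult(
            effect=factor_names[0], F=float(row["F"]),
            df_effect=float(row["DF"]),
            df_error=float(aov.loc[aov["Source"] == "Error", "DF"].iloc[0]),
            p=p, eta_p2=float(row["np2"]), gg_epsilon=gg_eps,
            mauchly_p=mauchly_p, gg_applied=gg_applied))
    else:
        aov = pg.rm_anova(data=df, dv="y", within=factor_names,
                          subject="subject", detailed=True, effsize="np2")
        # sphericity per factor (the two-way table reports no Mauchly test);
        # the interaction inherits a violation from either factor
        mauchly = {}
        for fi, fname in enumerate(factor_names):
            if data.shape[1 + fi] >= 3:
                collapsed = data.mean(axis=2 - fi)
                sub = _long_format(collapsed, [fname])
                mauchly[fname] = float(pg.sphericity(
                    data=sub, dv="y", within=fname, subject="subject").pval)
            else:
                mauchly[fname] = 1.0
        for _, row in aov.iterrows():
            src = str(row["Source"])
            violated = (any(mauchly[f] < 0.05 for f in factor_names)
                        if "*" in src else mauchly.get(src, 1.0) < 0.05)
            p = float(row["p_unc"])
            gg_applied = False
            if violated and np.isfinite(row.get("p_GG_corr", np.nan)):
                p = float(row["p_GG_corr"])
                gg_applied = True
            results.append(AnovaResult(
                effect=src, F=float(row["F"]),
                df_effect=float(row["ddof1"]), df_error=float(row["ddof2"]),
                p=p, eta_p2=float(row["np2"]), gg_epsilon=float(row["eps"]),
                mauchly_p=mauchly.get(src), gg_applied=gg_applied))
    return results


def permutation_pvalue(observed_r: float, null: NullDistribution,
                       two_tailed: bool = True) -> float:
    """Add-one permutation p-value against the shuffled-fold null."""
    if null.values.size == 0:
        raise ValueError("empty null distribution")
    if two_tailed:
        exceed = np.sum(np.abs(null.values) >= abs(observed_r))
    else:
        exceed = np.sum(null.values >= observed_r)
    return float((1 + exceed) / (null.n_iter + 1))
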