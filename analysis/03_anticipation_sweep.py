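"""Backward (decoding) analysis: how far ahead can steering be predicted?

Decodes the steering signal from progressively earlier 1.5 s EEG windows
(13 anticipations, 0-12 s) on the reference session and compares each
decoding correlation with the shuffled-fold null baseline. The null is
computed once and shared across anticipations: mispairing steering and EEG
folds destroys their alignment entirely, so the null does not depend on
the decoder's lag window. Finding: r decays with anticipation and falls
within the chance baseline by 12 s.
"""

import pathlib

import numpy as np
import pandas as pd

import steerdecode as sd
from steerdecode import session_io, stats, trf

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
GRID = tuple(np.logspace(-3, 9, 7))
NULL_ITER = 20


def main():
    sess = session_io.load_session(str(ROOT / "scratch" / "session.h5"))
    ants = list(trf.DEFAULT_ANTICIPATIONS)
    sweep = sd.anticipation_sweep(sess.eeg, sess.steering.values, ants, 1.5,
                                  sess.fs, lambda_grid=GRID, mode="global")
    cfg = trf.DecoderConfig(0.0, 1.5, sess.fs, GRID, 10, "global")
    null = stats.shuffled_fold_null(sess.eeg, sess.steering.values, cfg,
                                    NULL_ITER, seed=7000)
    b95 = stats.baseline_threshold(null, 95)

    rows = []
    for a, cv in sweep:
        rows.append({"anticipation_s": a, "mean_r": cv.mean_r,
                     "baseline95": b95, "above_baseline": cv.mean_r > b95,
                     "p_perm": stats.permutation_pvalue(cv.mean_r, null),
                     "lambda": cv.lambda_selected,
                     **{f"fold_{i}_r": r for i, r in enumerate(cv.fold_r)}})
        print(f"a = {a:5.1f} s   r = {cv.mean_r:+.3f}   "
              f"{'ABOVE' if cv.mean_r > b95 else 'within'} baseline "
              f"({b95:+.3f})")
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "anticipation_sweep.csv", index=False)
    last_above = df.loc[df["above_baseline"], "anticipation_s"].max()
    print(f"\ndecoding stays above chance up to {last_above:.1f} s of anticipation")


if __name__ == "__main__":
    main()
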