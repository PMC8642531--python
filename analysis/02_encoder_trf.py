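"""Forward (encoding) TRF analysis: does the EEG anticipate the action?

Fits steering->EEG lagged ridge models on the reference session, compares
the estimated temporal response functions against the generator's kernels,
and runs the group-level Wilcoxon+FDR analysis across several simulated
subjects. Finding: the TRF peaks several hundred ms *before* the steering
action, and the group mask recovers the anticipatory latencies.
"""

import pathlib

import numpy as np
import pandas as pd

import steerdecode as sd
from steerdecode import session_io, stats
from steerdecode.trf import LagWindow

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
GRID = tuple(np.logspace(-3, 9, 7))
N_SUBJECTS = 8


def main():
    RESULTS.mkdir(exist_ok=True)
    sess = session_io.load_session(str(ROOT / "scratch" / "session.h5"))
    gt_kernels = np.load(ROOT / "scratch" / "gt_kernels.npy")

    model, cv = sd.fit_encoder(sess.steering.values, sess.eeg,
                               LagWindow(-1.5, 0.5), sess.fs,
                               lambda_grid=GRID, mode="nested")
    lags = model.window.lags(sess.fs) / sess.fs
    trf_df = pd.DataFrame(model.weights[:, 0, :], columns=sess.eeg_labels)
    trf_df.insert(0, "lag_s", lags)
    trf_df.to_csv(RESULTS / "encoder_trf.csv", index=False)

    loaded = np.abs(gt_kernels).max(axis=1) > 0
    lag_sel = (lags >= -1.0) & (lags <= -0.3)
    recov = [np.corrcoef(gt_kernels[n, :], model.weights[lag_sel, 0, n])[0, 1]
             for n in np.flatnonzero(loaded)]
    print(f"encoder CV r = {cv.mean_r:.3f} (lambda {cv.lambda_selected:g})")
    print(f"kernel recovery on {loaded.sum()} loaded channels: "
          f"median |r| = {np.median(np.abs(recov)):.3f}")

    # group level: independent subjects share the anticipatory latencies
    # but have subject-specific channel loadings
    trfs = []
    for s in range(N_SUBJECTS):
        gt = sd.default_ground_truth(n_channels=8, fs=20, noise_sd=1.0,
                                     seed=900 + s, kernel_window=(-1.0, -0.3),
                                     bump_centers_s=(-0.75, -0.45),
                                     bump_widths_s=(0.10, 0.07),
                                     loaded_fraction=1.0)
        s_sess, _ = sd.generate_session(gt, 240, 20, seed=950 + s)
        m, _ = sd.fit_encoder(s_sess.steering.values, s_sess.eeg,
                              LagWindow(-1.5, 0.5), 20, lambda_grid=GRID,
                              mode="global", n_folds=5)
        trfs.append(m.weights[:, 0, :])
    stack = np.stack(trfs)
    # align signs across subjects (random loading polarity)
    ref = stack[0]
    for s in range(1, N_SUBJECTS):
        for c in range(stack.shape[2]):
            if np.dot(stack[s, :, c], ref[:, c]) < 0:
                stack[s, :, c] *= -1
    mask = stats.encoder_group_significance(stack, alpha=0.05)
    lags20 = LagWindow(-1.5, 0.5).lags(20) / 20
    sig = pd.DataFrame(mask, columns=[f"ch{c}" for c in range(mask.shape[1])])
    sig.insert(0, "lag_s", lags20)
    sig.to_csv(RESULTS / "encoder_group_significance.csv", index=False)
    sig_lags = lags20[mask.any(axis=1)]
    peak_lag = lags20[np.argmax(np.abs(stack.mean(axis=0)).max(axis=1))]
    print(f"group-significant latencies span [{sig_lags.min():.2f}, "
          f"{sig_lags.max():.2f}] s; group TRF peaks at {peak_lag:.2f} s "
          f"(anticipatory kernel support [-1.0, -0.3] s; serial correlation "
          f"of the steering smears significance beyond it)")


if __name__ == "__main__":
    main()
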