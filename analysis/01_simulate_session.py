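"""Generate the reference synthetic driving session used by the later
analysis steps and export its steering trace.

Writes the HDF5 session container to scratch/ (regenerable binary) and a
small steering CSV plus a ground-truth summary to results/.
"""

import json
import pathlib

import numpy as np

import steerdecode as sd
from steerdecode import session_io

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 2025

# study conditions: 10-minute drive, 25 Hz analysis rate, 24 EEG channels,
# anticipatory kernels in [-1.0, -0.3] s, unit 1/f noise, moderate
# instantaneous artifact leakage from EMG/accelerometers/EOG
GT_KW = dict(n_channels=24, fs=25.0, kernel_window=(-1.0, -0.3),
             bump_centers_s=(-0.75, -0.45), bump_widths_s=(0.10, 0.07),
             loaded_fraction=0.5, noise_sd=1.0,
             artifact_gains={"emg": 0.8, "accel": 1.0, "eog": 1.0})
DURATION_S = 600.0


def main():
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    gt = sd.default_ground_truth(seed=SEED, **GT_KW)
    sess, gt = sd.generate_session(gt, DURATION_S, GT_KW["fs"], seed=SEED + 1)

    session_io.save_session(sess, str(SCRATCH / "session.h5"))
    session_io.save_steering_csv(
        sd.SteeringSignal(sess.steering.values[: int(60 * sess.fs)], sess.fs),
        str(RESULTS / "steering_first_minute.csv"))
    np.save(SCRATCH / "gt_kernels.npy", gt.kernels)

    summary = {
        "duration_s": DURATION_S, "fs": sess.fs,
        "n_eeg_channels": sess.n_channels,
        "n_loaded_channels": int((np.abs(gt.kernels).max(axis=1) > 0).sum()),
        "kernel_window_s": list(gt.kernel_window),
        "artifact_gains": gt.artifact_gains, "noise_sd": gt.noise_sd,
        "eog_lead_s": gt.eog_lead_s, "seed": SEED,
    }
    with open(RESULTS / "session_summary.json", "w") as f:
        json.dump(summary, f, indent=2)
    print("simulated session:", summary)


if __name__ == "__main__":
    main()
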