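import numpy as np
import pytest

import steerdecode as sd


@pytest.fixture(scope="session")
def small_session():
    """Modest brain-only session (no artifacts) shared across tests."""
    gt = sd.default_ground_truth(n_channels=6, fs=25, noise_sd=1.0, seed=100,
                                 loaded_fraction=0.5)
    sess, gt = sd.generate_session(gt, 120, 25, seed=101)
    return sess, gt


@pytest.fixture(scope="session")
def noiseless_session():
    """Noiseless, artifact-free session: EEG is exactly kernel (*) steering."""
    gt = sd.default_ground_truth(n_channels=4, fs=50, noise_sd=0.0, seed=7,
                                 loaded_fraction=0.75)
    sess, gt = sd.generate_session(gt, 120, 50, seed=8)
    return sess, gt
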