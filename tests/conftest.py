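import numpy as np
import pytest

import oscpipe as op


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale two-participant simulation shared across tests."""
    cfg = op.SimConfig(n_participants=2, n_trials=64, n_channels=16,
                       fs=150.0, epoch_s=(-1.0, 6.0), seed=11)
    ts, gt = op.simulate(cfg)
    return ts, gt, cfg


@pytest.fixture
def grid16():
    return op.SensorLayout.grid(4, 4)


@pytest.fixture
def tone_trialset():
    """3 trials x 4 channels of a pure 10 Hz tone at 150 Hz."""
    fs = 150.0
    times = np.arange(-1.0, 3.0, 1 / fs)
    data = np.tile(np.cos(2 * np.pi * 10 * times), (3, 4, 1))
    return op.TrialSet(data, fs, times, op.SensorLayout.grid(2, 2))
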