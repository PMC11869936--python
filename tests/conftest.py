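import numpy as np
import pytest

from voxelus import synth
from voxelus.core import TrialSet


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Small noiseless dataset: recovery must be exact."""
    return synth.SynthConfig(grid_shape=(20, 20), n_trials=5,
                             conditions=(5.0, 100.0), rng_seed=7)


@pytest.fixture(scope="session")
def noiseless_data(noiseless_cfg):
    return synth.generate(noiseless_cfg)


@pytest.fixture(scope="session")
def noisy_cfg():
    return synth.SynthConfig(grid_shape=(20, 20), n_trials=20,
                             conditions=(10.0, 100.0),
                             trial_gain_sd=0.02, frame_noise_sd_percent=2.0,
                             rng_seed=11)


@pytest.fixture(scope="session")
def noisy_data(noisy_cfg):
    return synth.generate(noisy_cfg)


def make_trialset(values, frame_interval_s=0.6, baseline_s=10.0, stimulus_s=4.0,
                  post_s=20.0, conditions=(100.0,), subject_id="t"):
    """Wrap a (nz, nx, frames[, trials[, conditions]]) array into a TrialSet."""
    arr = np.asarray(values, dtype=float)
    while arr.ndim < 5:
        arr = arr[..., None]
    return TrialSet(intensity=arr, frame_interval_s=frame_interval_s,
                    baseline_s=baseline_s, stimulus_s=stimulus_s, post_s=post_s,
                    conditions=conditions, subject_id=subject_id)


@pytest.fixture
def timing_ts():
    """A timing-only TrialSet: 57 frames of flat baseline-100 intensity."""
    return make_trialset(np.full((1, 1, 57), 100.0))
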