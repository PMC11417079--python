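import numpy as np
import pytest

import decaymap as dm
from decaymap.presets import train_scaled_down_models

STUDY_SEED = 11


@pytest.fixture(scope="session")
def schedule():
    return dm.EchoSchedule.default_synthetic()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_records():
    """A handful of tiny urand records for plumbing tests."""
    cfg = dm.SynthConfig(n_series=4, size=8, mode="urand", seed=3)
    return dm.build_synthetic_dataset(cfg)


@pytest.fixture(scope="session")
def trained():
    """The scaled-down study: corpus-trained CNN, urand-trained NN1D, test sets.

    Trained once per session; shared by the estimator-comparison tests.
    """
    return train_scaled_down_models(seed=STUDY_SEED)


def per_slice_accuracy(pmap, truth) -> float:
    """Median absolute T error over one map."""
    return float(np.median(np.abs(pmap.t - truth.t)))
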