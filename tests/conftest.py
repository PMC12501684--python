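"""Shared fixtures: micro phantoms, scans and a session-scoped trained model.

All fixtures are generated programmatically; training runs once per session
at micro scale and is reused by every test that needs a fitted denoiser.
"""

import numpy as np
import pytest

from asldenoise import (AcquisitionParams, make_cohort, make_phantom,
                        simulate_series)
from asldenoise.experiments import split_cohort, train_for_condition
from asldenoise.model import micro_config
from asldenoise.training import micro_schedule

MICRO_SHAPE = (16, 16, 8)


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(MICRO_SHAPE, seed=7)


@pytest.fixture(scope="session")
def scan(phantom):
    return simulate_series(
        phantom, AcquisitionParams(n_timepoints=32, snr_regime="high",
                                   seed=7))


@pytest.fixture(scope="session")
def low_snr_scan(phantom):
    return simulate_series(
        phantom, AcquisitionParams(n_timepoints=32, snr_regime="low",
                                   seed=7))


@pytest.fixture(scope="session")
def cohort():
    return make_cohort(n_subjects=12, n_low=4, shape=MICRO_SHAPE,
                       n_timepoints=32, seed=5)


@pytest.fixture(scope="session")
def trained_model(cohort):
    """A micro denoiser trained at N_av = 1 (the noisiest condition)."""
    train, val, _ = split_cohort(cohort, seed=5)
    return train_for_condition(
        train, val, n_av_train=1, model_cfg=micro_config(),
        schedule=micro_schedule(seed=5), max_samples=64, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
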