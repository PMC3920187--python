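"""Shared fixtures.

The full-size (5000-trial) control and patient ensembles are expensive, so
they are computed once per session and shared by the acceptance tests.
"""

import numpy as np
import pytest

from saccade_race import analysis
from saccade_race.experiment import (
    control_condition,
    patient_condition,
    run_ensemble,
)
from saccade_race.network import NetworkParams, build_kernel

ACCEPTANCE_SEED = 20_140_211
ACCEPTANCE_NTRIALS = 5000


@pytest.fixture(scope="session")
def control_ensemble():
    return run_ensemble(
        control_condition(), ntrials=ACCEPTANCE_NTRIALS, master_seed=ACCEPTANCE_SEED
    )


@pytest.fixture(scope="session")
def patient_ensemble():
    return run_ensemble(
        patient_condition(), ntrials=ACCEPTANCE_NTRIALS, master_seed=ACCEPTANCE_SEED + 1
    )


@pytest.fixture(scope="session")
def control_summary(control_ensemble):
    return analysis.summarize(control_ensemble)


@pytest.fixture(scope="session")
def patient_summary(patient_ensemble):
    return analysis.summarize(patient_ensemble)


@pytest.fixture(scope="session")
def tiny_control_ensemble():
    return run_ensemble(control_condition(), ntrials=40, master_seed=7)


@pytest.fixture()
def default_params():
    return NetworkParams()


@pytest.fixture()
def calibrated_params():
    return control_condition().resolve()


@pytest.fixture()
def calibrated_kernel(calibrated_params):
    return build_kernel(calibrated_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
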