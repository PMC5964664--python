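import numpy as np
import pytest

from augbin import (
    AnalysisConfig,
    TrialDataset,
    calibrate_generator,
    default_generator_params,
)


@pytest.fixture(scope="session")
def base_params():
    return default_generator_params()


@pytest.fixture(scope="session")
def alt_params(base_params):
    """Generator calibrated to the alternative response rates 0.470 / 0.336."""
    return calibrate_generator(0.470, 0.336, base_params)


@pytest.fixture(scope="session")
def null_params(base_params):
    """Generator calibrated to equal response rates 0.336 / 0.336."""
    return calibrate_generator(0.336, 0.336, base_params)


@pytest.fixture
def toy_dataset():
    """4 patients, T=2, threshold 20: responders are patients 1 and 3."""
    return TrialDataset(
        patient_id=np.array(["p1", "p2", "p3", "p4"], dtype=object),
        arm=np.array([1, 0, 1, 0]),
        baseline=np.array([50.0, 45.0, 55.0, 60.0]),
        y=np.array([[10.0, 25.0], [5.0, 10.0], [15.0, 30.0], [0.0, np.nan]]),
        d=np.array([[0, 0], [0, 0], [0, 0], [0, 1]]),
        threshold=20.0,
    )


def make_two_by_two(n1, e1, n0, e0, threshold=20.0):
    """Trial whose responder flags form a 2x2 table: e1/n1 vs e0/n0.

    Final-visit outcomes are pushed far above/below the threshold so the
    responder derivation reproduces the requested counts exactly.
    """
    n = n1 + n0
    arm = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
    resp = np.concatenate(
        [np.r_[np.ones(e1), np.zeros(n1 - e1)], np.r_[np.ones(e0), np.zeros(n0 - e0)]]
    )
    y_final = np.where(resp == 1, threshold + 30.0, threshold - 30.0)
    y = np.column_stack([np.zeros(n), y_final])
    return TrialDataset(
        patient_id=np.array([f"t{i}" for i in range(n)], dtype=object),
        arm=arm,
        baseline=np.full(n, 50.0),
        y=y,
        d=np.zeros((n, 2), dtype=int),
        threshold=threshold,
    )


@pytest.fixture
def two_by_two():
    """8/10 events on treatment vs 2/10 on control."""
    return make_two_by_two(10, 8, 10, 2)


@pytest.fixture
def default_config():
    return AnalysisConfig()
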