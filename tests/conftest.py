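import numpy as np
import pytest

from abps import CohortSpec, MARKERS, generate_cohort_frame, train_default_model


@pytest.fixture(scope="session")
def default_model():
    """Ensemble trained on the default 402+189 synthetic cohort and
    calibrated on an independent clean reference population."""
    return train_default_model(seed=0, calibration_size=5_000)


@pytest.fixture(scope="session")
def cohort_frame():
    return generate_cohort_frame(CohortSpec(seed=123))


@pytest.fixture(scope="session")
def cohort_matrix(cohort_frame):
    X = cohort_frame[list(MARKERS)].to_numpy(float)
    y = cohort_frame["label"].to_numpy()
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(20180)
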