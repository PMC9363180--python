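import numpy as np
import pytest

from hillhip.calibration import GAConfig, calibrate, forward_moment
from hillhip.hip_geometry import HipAnthropometry, HipModelParams, default_muscle_set
from hillhip.synthetic_gait import GaitGenConfig, generate_from_model, generate_gait

#: known "true" hip-model parameters for recovery experiments
TRUE_H = dict(
    betas=np.radians([60.0, 80.0, 120.0, 100.0, 85.0, 70.0]),
    m_scale=1.15,
    n_scale=0.85,
)

#: small but sufficient GA budget for test-time calibrations (the bounded
#: least-squares polish does the fine work)
TEST_GA = GAConfig(population=24, generations=30)


@pytest.fixture(scope="session")
def anthro():
    return HipAnthropometry.default()


@pytest.fixture(scope="session")
def muscles(anthro):
    return default_muscle_set(anthro)


@pytest.fixture(scope="session")
def default_gait():
    return generate_gait(GaitGenConfig(seed=0))


@pytest.fixture(scope="session")
def truth_model():
    return HipModelParams(**TRUE_H)


@pytest.fixture(scope="session")
def model_gait(truth_model, muscles, anthro, default_gait):
    """Noiseless model-consistent gait plus its ground-truth record."""
    return generate_from_model(truth_model, muscles, anthro, default_gait)


@pytest.fixture(scope="session")
def recovery_calibration(model_gait, muscles, anthro):
    gait, _ = model_gait
    return calibrate(gait, muscles, anthro, ga_config=TEST_GA, seed=11)


@pytest.fixture(scope="session")
def default_calibration(default_gait, muscles, anthro):
    """Calibration against the default synthetic gait (imperfect fit)."""
    return calibrate(default_gait, muscles, anthro, ga_config=TEST_GA, seed=5)


@pytest.fixture(scope="session")
def default_baseline(default_gait, default_calibration, anthro):
    c = default_calibration
    return forward_moment(default_gait, c.model, c.muscles, anthro)
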