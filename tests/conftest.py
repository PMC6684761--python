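import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coact.gait_model import (MuscleGeometry, PlanarSegmentModel,
                              generate_normative_gait)
from coact.muscle_model import max_achievable_forces
from coact.muscles import default_muscle_params

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def segment_model():
    return PlanarSegmentModel.default_adult()


@pytest.fixture(scope="session")
def geometry():
    return MuscleGeometry.default()


@pytest.fixture(scope="session")
def trial(segment_model, geometry):
    """Default 101-sample synthetic normative gait cycle."""
    return generate_normative_gait(segment_model, geometry, n_samples=101,
                                   cycle_duration=1.2, seed=1)


@pytest.fixture(scope="session")
def small_trial(segment_model, geometry):
    """Coarse trial for tests where solve time dominates."""
    return generate_normative_gait(segment_model, geometry, n_samples=21,
                                   cycle_duration=1.2, seed=1)


@pytest.fixture(scope="session")
def params():
    return default_muscle_params()


@pytest.fixture(scope="session")
def maxforce(trial, params):
    return max_achievable_forces(trial, params)


@pytest.fixture(scope="session")
def small_maxforce(small_trial, params):
    return max_achievable_forces(small_trial, params)
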