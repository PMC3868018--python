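import numpy as np
import pytest

from advicerl import ScheduleConfig, generate_schedule, extract_outcomes
from advicerl.learners import LearnerGrid
from advicerl.inference import FitGrid


@pytest.fixture(scope="session")
def schedule():
    """One default 290-trial session, fixed seed."""
    return generate_schedule(ScheduleConfig(seed=7))


@pytest.fixture(scope="session")
def outcomes(schedule):
    return extract_outcomes(schedule)


@pytest.fixture(scope="session")
def small_learner_grid():
    """Coarse latent grid used where tracker resolution is not under test."""
    return LearnerGrid(r_points=20, v_points=15, k_points=12)


@pytest.fixture(scope="session")
def fast_fit_grid():
    return FitGrid(points_per_dim=30)
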