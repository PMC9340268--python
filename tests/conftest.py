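import numpy as np
import pytest

from interactsim import (
    Cohort,
    CovariateModel,
    CovariatePredictor,
    SCENARIOS,
    calibrated_model,
)
from interactsim.cohort import WOMAN_PREVALENCE


def make_cohort(columns, x, y, scenario_name="") -> Cohort:
    return Cohort(
        x=np.asarray(x), y=np.asarray(y), columns=tuple(columns),
        scenario_name=scenario_name,
    )


def tiny_model(diet_prev=0.5, diet_log_or=0.0, woman_log_or=0.0,
               extra=(), intercept=None) -> CovariateModel:
    """A minimal valid model: diet + woman (+ optional adjusters)."""
    predictors = [
        CovariatePredictor("diet", diet_prev, diet_log_or, role="diet"),
        CovariatePredictor("woman", WOMAN_PREVALENCE, woman_log_or, role="woman"),
        *extra,
    ]
    return CovariateModel(predictors=tuple(predictors), intercept=intercept)


@pytest.fixture(scope="session")
def small_scenario():
    return SCENARIOS["small"]


@pytest.fixture(scope="session")
def default_small_model():
    return calibrated_model("small")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
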