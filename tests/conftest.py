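import numpy as np
import pytest

from obesim.params import (
    ALIVE_CATEGORIES,
    MAX_AGE,
    N_AGES,
    BmiCategory,
    CostSchedule,
    InterventionEffect,
    MortalityInputs,
    ParameterSet,
    RelativeRisk,
    RunConfig,
    Sex,
    TransitionTable,
    UtilitySchedule,
)
from obesim.synth import make_truth


@pytest.fixture(scope="session")
def baseline_truth():
    return make_truth("baseline", seed=42)


@pytest.fixture(scope="session")
def null_truth():
    return make_truth("null-effect", seed=42)


@pytest.fixture(scope="session")
def strong_truth():
    return make_truth("strong-effect", seed=42)


@pytest.fixture()
def config():
    return RunConfig(seed=1)


def make_toy_params(
    normal_row=(1.0, 0.0, 0.0, 0.0),
    ow_row=(0.0, 1.0, 0.0, 0.0),
    ob_row=(0.0, 0.0, 1.0, 0.0),
    qx_value=0.0,
    cost_value=0.0,
    utility_value=1.0,
    initial=(1.0, 0.0, 0.0),
    rr_adult_ow=1.0,
    rr_adult_ob=1.0,
    rr_history=1.0,
    effect=None,
) -> ParameterSet:
    """Uniform-in-age toy parameter set for hand-computable scenarios."""
    common = np.zeros((2, N_AGES, 4, 4))
    for row_idx, row in zip(range(3), (normal_row, ow_row, ob_row)):
        common[:, :, row_idx, :] = np.asarray(row, dtype=float)
    common[:, :, BmiCategory.DEAD, BmiCategory.DEAD] = 1.0
    qx = np.full((2, MAX_AGE + 1), float(qx_value))
    cost_mean = np.full((2, N_AGES, 3, 2), float(cost_value) / 2.0)
    util_mean = np.full((2, N_AGES, 3), float(utility_value))
    params = ParameterSet(
        transitions=TransitionTable(common=common),
        effect=effect or InterventionEffect(
            rr_overweight=RelativeRisk(1.0, 1.0, 1.0),
            rr_obese=RelativeRisk(1.0, 1.0, 1.0),
        ),
        mortality=MortalityInputs(
            qx=qx,
            rr_adult_ow=RelativeRisk(rr_adult_ow, rr_adult_ow, rr_adult_ow),
            rr_adult_ob=RelativeRisk(rr_adult_ob, rr_adult_ob, rr_adult_ob),
            rr_childhood_history=RelativeRisk(rr_history, rr_history, rr_history),
        ),
        costs=CostSchedule(mean=cost_mean, se=np.zeros_like(cost_mean)),
        utilities=UtilitySchedule(mean=util_mean, se=np.zeros_like(util_mean)),
        initial=np.array([initial, initial], dtype=float),
    )
    params.validate()
    return params


@pytest.fixture()
def toy_params():
    return make_toy_params()
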