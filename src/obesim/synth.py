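"""Synthetic model inputs with known ground truth.

Stands in for the trial/survey-derived parameter tables: a smooth,
age/sex-varying transition structure (childhood incidence rising with age,
adult prevalence drifting up to mid-life), a life table with mortality
increasing in age, cost schedules ordered OBESE > OVERWEIGHT > NORMAL at
every age, utilities decreasing in BMI category and age, and an
intervention effect profile.  Also simulates trial-like longitudinal
category panels from the truth for estimator testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    ALIVE_CATEGORIES,
    MAX_AGE,
    N_AGES,
    Arm,
    BmiCategory,
    CostSchedule,
    InterventionEffect,
    MortalityInputs,
    ParameterSet,
    RelativeRisk,
    Sex,
    TransitionTable,
    UtilitySchedule,
    write_parameters,
)
from .transitions import PANEL_COLUMNS

logger = logging.getLogger(__name__)

PROFILES = ("baseline", "strong-effect", "null-effect")


@dataclass
class SyntheticTruth:
    """A complete generated ParameterSet plus its provenance (profile, seed)."""

    params: ParameterSet
    profile: str
    seed: int

    # convenience views onto the embedded parameter set
    @property
    def true_transitions(self) -> TransitionTable:
        return self.params.transitions

    @property
    def true_effect(self) -> InterventionEffect:
        return self.params.effect

    @property
    def true_mortality(self) -> MortalityInputs:
        return self.params.mortality

    @property
    def true_costs(self) -> CostSchedule:
        return self.params.costs

    @property
    def true_utilities(self) -> UtilitySchedule:
        return self.params.utilities


def _smooth_noise(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Low-frequency multiplicative wiggle in [1-scale, 1+scale]."""
    knots = rng.uniform(-1.0, 1.0, size=8)
    x = np.linspace(0, 7, n)
    wig = np.interp(x, np.arange(8), knots)
    return 1.0 + scale * wig


def _transition_matrices(rng: np.random.Generator) -> np.ndarray:
    """COMMON matrices (2, N_AGES, 4, 4); death column is zero (life table rules)."""
    ages = np.arange(N_AGES, dtype=float)
    common = np.zeros((2, N_AGES, 4, 4))
    for sex in Sex:
        sex_shift = 1.0 if sex is Sex.MALE else 0.92
        # incidence out of NORMAL: rises through childhood, adult drift peaks mid-life
        child_ow = 0.015 + 0.004 * np.minimum(ages, 17)
        adult_ow = 0.030 + 0.020 * np.exp(-0.5 * ((ages - 45.0) / 18.0) ** 2)
        p_n_ow = np.where(ages < 18, child_ow, adult_ow) * sex_shift
        p_n_ow *= _smooth_noise(rng, N_AGES, 0.10)
        p_n_ob = 0.35 * p_n_ow * _smooth_noise(rng, N_AGES, 0.10)
        # remission out of OVERWEIGHT, decreasing with age
        p_ow_n = (0.20 * np.exp(-ages / 35.0) + 0.04) * _smooth_noise(rng, N_AGES, 0.10)
        p_ow_ob = (0.05 + 0.0008 * np.minimum(ages, 60)) * _smooth_noise(rng, N_AGES, 0.10)
        # movement out of OBESE
        p_ob_ow = (0.08 * np.exp(-ages / 50.0) + 0.03) * _smooth_noise(rng, N_AGES, 0.10)
        p_ob_n = 0.25 * p_ob_ow

        m = common[sex]
        m[:, 0, 1] = p_n_ow
        m[:, 0, 2] = p_n_ob
        m[:, 0, 0] = 1.0 - p_n_ow - p_n_ob
        m[:, 1, 0] = p_ow_n
        m[:, 1, 2] = p_ow_ob
        m[:, 1, 1] = 1.0 - p_ow_n - p_ow_ob
        m[:, 2, 0] = p_ob_n
        m[:, 2, 1] = p_ob_ow
        m[:, 2, 2] = 1.0 - p_ob_n - p_ob_ow
        m[:, 3, 3] = 1.0
    return common


def _life_table(rng: np.random.Generator) -> np.ndarray:
    """qx (2, MAX_AGE + 1): infant bump, low plateau, then exponential rise."""
    ages = np.arange(MAX_AGE + 1, dtype=float)
    qx = np.empty((2, MAX_AGE + 1))
    for sex in Sex:
        level = 1.0 if sex is Sex.MALE else 0.85
        infant = 0.0035 * np.exp(-ages / 1.5)
        background = 1.5e-4 + 2.0e-5 * ages
        gompertz = 2.2e-5 * np.exp(0.096 * ages)
        qx[sex] = np.minimum((infant + background + gompertz) * level, 0.95)
    return qx


def _cost_schedule(rng: np.random.Generator) -> CostSchedule:
    ages = np.arange(N_AGES, dtype=float)
    mean = np.zeros((2, N_AGES, 3, 2))
    for sex in Sex:
        sex_f = 1.0 if sex is Sex.MALE else 1.08
        ramp = 0.35 + 0.65 * np.minimum(ages / 60.0, 1.0)
        working = np.exp(-0.5 * ((ages - 45.0) / 16.0) ** 2)  # indirect cost window
        base_direct = {0: 25.0, 1: 420.0, 2: 1150.0}
        base_indirect = {0: 10.0, 1: 300.0, 2: 900.0}
        for state in ALIVE_CATEGORIES:
            mean[sex, :, state, 0] = base_direct[int(state)] * ramp * sex_f
            mean[sex, :, state, 1] = base_indirect[int(state)] * working * sex_f
    mean *= _smooth_noise(rng, N_AGES, 0.05)[None, :, None, None]
    se = 0.20 * mean
    return CostSchedule(mean=mean, se=se)


def _utility_schedule(rng: np.random.Generator) -> UtilitySchedule:
    ages = np.arange(N_AGES, dtype=float)
    mean = np.full((2, N_AGES, 3), np.nan)
    decrements = {0: 0.0, 1: 0.02, 2: 0.06}
    for sex in Sex:
        base = 0.95 - 0.0028 * np.maximum(ages - 18.0, 0.0)
        base *= 1.0 if sex is Sex.MALE else 0.995
        for state in ALIVE_CATEGORIES:
            mean[sex, :, state] = np.clip(base - decrements[int(state)], 0.05, 1.0)
    mean[:, :18, :] = np.nan  # quality of life modelled from adolescence on
    se = np.zeros_like(mean)
    se[:, 18:, :] = 0.01
    return UtilitySchedule(mean=np.round(mean, 12), se=se)


_EFFECTS = {
    "baseline": InterventionEffect(
        rr_overweight=RelativeRisk(0.72, 0.55, 0.94),
        rr_obese=RelativeRisk(0.62, 0.44, 0.88),
        duration_years=6,
    ),
    "strong-effect": InterventionEffect(
        rr_overweight=RelativeRisk(0.45, 0.30, 0.68),
        rr_obese=RelativeRisk(0.35, 0.20, 0.60),
        duration_years=6,
    ),
    "null-effect": InterventionEffect(
        rr_overweight=RelativeRisk(1.0, 1.0, 1.0),
        rr_obese=RelativeRisk(1.0, 1.0, 1.0),
        duration_years=6,
    ),
}


def make_truth(profile: str, seed: int, initial_owob: float = 0.02) -> SyntheticTruth:
    """Generate a complete synthetic ParameterSet for a named profile.

    Profiles share the generation recipe and differ in the intervention
    relative risks: ``baseline`` a moderate protective effect,
    ``strong-effect`` a large one, ``null-effect`` exactly 1 (degenerate CI).
    Regeneration with the same seed is bitwise identical.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB31)))

    common = _transition_matrices(rng)
    mortality = MortalityInputs(
        qx=_life_table(rng),
        rr_adult_ow=RelativeRisk(1.15, 1.02, 1.30),
        rr_adult_ob=RelativeRisk(1.45, 1.20, 1.75),
        rr_childhood_history=RelativeRisk(1.12, 1.01, 1.25),
    )
    costs = _cost_schedule(rng)
    utilities = _utility_schedule(rng)
    # newborn cohort: overweight/obese mass near zero
    initial = np.array([
        [1.0 - initial_owob, 0.75 * initial_owob, 0.25 * initial_owob],
        [1.0 - initial_owob, 0.75 * initial_owob, 0.25 * initial_owob],
    ])

    params = ParameterSet(
        transitions=TransitionTable(common=common),
        effect=_EFFECTS[profile],
        mortality=mortality,
        costs=costs,
        utilities=utilities,
        initial=initial,
    )
    params.validate()
    return SyntheticTruth(params=params, profile=profile, seed=seed)


def simulate_panel(
    truth: SyntheticTruth,
    n_per_arm: int,
    seed: int,
    max_age: int = 6,
    dropout_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate a trial-like longitudinal category panel from the truth.

    Each subject is assigned a sex (50/50), starts from the truth's initial
    distribution and evolves annually under the arm's transition matrices
    (LP matrices include the intervention effect).  After the age-0 visit a
    subject drops out before each subsequent visit with probability
    ``dropout_rate``; dropout is monotone (no return visits).
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    if not (0.0 <= dropout_rate <= 1.0):
        raise ValueError("dropout_rate must be in [0, 1]")
    from .engine import _alive_blocks, build_arm_matrices  # deferred: avoids cycle

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11)))
    records = []
    subject = 0
    for arm in (Arm.LP, Arm.HP):
        blocks = {
            sex: _alive_blocks(build_arm_matrices(truth.params, arm, sex)) for sex in Sex
        }
        for _ in range(n_per_arm):
            sex = Sex(int(rng.integers(0, 2)))
            state = int(rng.choice(3, p=truth.params.initial[sex]))
            records.append((f"S{subject:06d}", arm.value, sex.name, 0,
                            BmiCategory(state).name))
            for age in range(max_age):
                if dropout_rate > 0.0 and rng.random() < dropout_rate:
                    break
                state = int(rng.choice(3, p=blocks[sex][age, state]))
                records.append((f"S{subject:06d}", arm.value, sex.name, age + 1,
                                BmiCategory(state).name))
            subject += 1
    return pd.DataFrame.from_records(records, columns=PANEL_COLUMNS)


def write_bundle(truth: SyntheticTruth, directory) -> dict:
    """Write the truth's CSV bundle; loadable back losslessly."""
    paths = write_parameters(truth.params, directory)
    logger.info("wrote synthetic bundle (%s, seed %d) to %s", truth.profile, truth.seed, directory)
    return paths
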