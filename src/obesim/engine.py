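"""Two-part Markov cohort engine.

The childhood-to-adolescence model (M1) propagates the cohort from age 0 to
age 18 with arm-specific transition matrices during the intervention effect
window and life-table mortality applied uniformly across BMI states; anyone
who ever occupies overweight or obese carries an EVER history flag from
then on.  The adulthood model (M2) continues from the age-18 hand-off to the
horizon, with mortality multiplied by adult overweight/obesity relative
risks and the childhood-history relative risk.  Costs accrue per (age, sex,
category); utilities accrue from the QALY start age (18 by default).  State
membership is evaluated at cycle start and rewards accrue for the full year
(no half-cycle correction); discounting is referenced to birth (cycle 0 =
age 0).

Expanded-state vectors are laid out as 8 entries: history blocks
(NEVER, EVER) of the four ``BmiCategory`` entries, i.e. index
``hist * 4 + category``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .params import (
    M1_END_AGE,
    N_AGES,
    ROW_SUM_TOL,
    Arm,
    BmiCategory,
    ParameterSet,
    RunConfig,
    Sex,
)
from .transitions import apply_relative_risk

logger = logging.getLogger(__name__)

HIST_NEVER = 0
HIST_EVER = 1
N_EXPANDED = 8

#: Expanded-state column labels in vector order.
EXPANDED_LABELS = tuple(
    (hist, cat) for hist in ("NEVER_OWOB", "EVER_OWOB") for cat in BmiCategory
)

_OW = int(BmiCategory.OVERWEIGHT)
_OB = int(BmiCategory.OBESE)
_DEAD = int(BmiCategory.DEAD)


def discount(amount: float, cycle: int, rate: float) -> float:
    """Present value at birth of ``amount`` accruing in ``cycle`` (years)."""
    if cycle < 0:
        raise ValueError(f"cycle must be >= 0, got {cycle}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return float(amount) / (1.0 + rate) ** int(cycle)


@dataclass
class CohortTrace:
    """Per-cycle occupancy and discounted reward increments for one arm/sex.

    ``occupancy[i]`` is the expanded-state distribution at ``ages[i]``;
    ``disc_cost[i]``/``disc_qaly[i]`` are the discounted increments accrued
    over the cycle starting at ``ages[i]`` (one fewer entry than ages).
    """

    arm: Arm
    sex: Sex
    ages: np.ndarray          # (n + 1,)
    occupancy: np.ndarray     # (n + 1, 8)
    disc_cost: np.ndarray     # (n,)
    disc_qaly: np.ndarray     # (n,)

    def validate(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.abs(sums - 1.0).max() > ROW_SUM_TOL:
            raise ValueError(f"occupancy must sum to 1 every cycle (max dev {np.abs(sums - 1).max():.3g})")
        dead = self.occupancy[:, _DEAD] + self.occupancy[:, 4 + _DEAD]
        if np.any(np.diff(dead) < -ROW_SUM_TOL):
            raise ValueError("DEAD mass must be non-decreasing")

    @property
    def alive_mass(self) -> np.ndarray:
        alive_cols = [0, 1, 2, 4, 5, 6]
        return self.occupancy[:, alive_cols].sum(axis=1)

    @property
    def owob_mass(self) -> np.ndarray:
        return self.occupancy[:, [_OW, _OB, 4 + _OW, 4 + _OB]].sum(axis=1)


@dataclass
class ArmResult:
    """Discounted lifetime totals per person for one strategy (one or mixed sexes)."""

    lifetime_cost_pp: float
    lifetime_qaly_pp: float
    person_years_owob: float
    decade_costs: np.ndarray  # (10,) discounted cost per decade of life
    life_expectancy: float

    def validate(self, horizon: float = float(N_AGES)) -> None:
        if not np.isclose(self.decade_costs.sum(), self.lifetime_cost_pp, rtol=1e-6, atol=1e-9):
            raise ValueError("decade costs must sum to the lifetime cost")
        if not (0.0 <= self.person_years_owob <= self.life_expectancy + 1e-9):
            raise ValueError("person-years in OW/OB must not exceed life expectancy")
        if self.life_expectancy > horizon + 1e-9:
            raise ValueError("life expectancy exceeds the model horizon")

    def to_dict(self) -> dict:
        return {
            "lifetime_cost_pp": float(self.lifetime_cost_pp),
            "lifetime_qaly_pp": float(self.lifetime_qaly_pp),
            "person_years_owob": float(self.person_years_owob),
            "decade_costs": [float(c) for c in self.decade_costs],
            "life_expectancy": float(self.life_expectancy),
        }


def build_arm_matrices(params: ParameterSet, arm: Arm, sex: Sex) -> np.ndarray:
    """Assemble the (N_AGES, 4, 4) matrix stack used by one arm and sex.

    Explicit arm-specific table entries win for ages inside the effect
    window; otherwise the LP arm applies the intervention relative risks to
    the COMMON NORMAL row for ages below ``duration_years``; the HP arm (and
    every age past the window) uses COMMON rows unchanged.
    """
    mats = params.transitions.common[sex].copy()
    table = params.transitions
    explicit = table.arm_specific.get(arm)
    window = params.effect.duration_years
    for age in range(min(window, N_AGES)):
        if explicit is not None and age < explicit.shape[1]:
            mats[age] = explicit[sex, age]
        elif arm is Arm.LP:
            mats[age, BmiCategory.NORMAL] = apply_relative_risk(
                mats[age, BmiCategory.NORMAL], params.effect
            )
    return mats


def _alive_blocks(mats: np.ndarray) -> np.ndarray:
    """Alive-to-alive sub-rows renormalised to exclude the death column.

    Mortality is governed exclusively by the life table (and its relative
    risks); a non-zero death column in a transition matrix therefore only
    shapes where survivors go.
    """
    death = mats[:, :3, _DEAD]
    alive = mats[:, :3, :3]
    denom = 1.0 - death
    out = np.divide(alive, denom[..., None], out=np.zeros_like(alive), where=denom[..., None] > 0)
    return out


def _initial_expanded(initial_sex: np.ndarray) -> np.ndarray:
    """Age-0 expanded vector: overweight/obese starters already carry history."""
    x = np.zeros(N_EXPANDED)
    x[HIST_NEVER * 4 + BmiCategory.NORMAL] = initial_sex[BmiCategory.NORMAL]
    x[HIST_EVER * 4 + _OW] = initial_sex[_OW]
    x[HIST_EVER * 4 + _OB] = initial_sex[_OB]
    return x


def _propagate(
    params: ParameterSet,
    arm: Arm,
    sex: Sex,
    config: RunConfig,
    age_start: int,
    age_end: int,
    x0: np.ndarray,
) -> CohortTrace:
    """Shared cycle loop for M1 and M2 over ages [age_start, age_end)."""
    if abs(x0.sum() - 1.0) > ROW_SUM_TOL:
        raise ValueError(f"starting distribution must sum to 1, got {x0.sum():.12g}")
    mats = build_arm_matrices(params, arm, sex)
    A = _alive_blocks(mats)  # (N_AGES, 3, 3)
    qx = params.mortality.qx[sex]
    cost_total = params.costs.annual_total(sex)          # (N_AGES, 3)
    util = params.utilities.mean[sex]                    # (N_AGES, 3)
    qaly_start = params.utilities.child_qaly_start_age
    rate = config.discount_rate
    df = (1.0 + rate) ** -np.arange(N_AGES, dtype=float)

    rr_cat = np.array([
        1.0,
        params.mortality.rr_adult_ow.value,
        params.mortality.rr_adult_ob.value,
    ])
    rr_hist = np.array([1.0, params.mortality.rr_childhood_history.value])

    n = age_end - age_start
    occupancy = np.empty((n + 1, N_EXPANDED))
    disc_cost = np.zeros(n)
    disc_qaly = np.zeros(n)

    alive = x0.reshape(2, 4)[:, :3].copy()   # (hist, cat)
    dead = x0.reshape(2, 4)[:, 3].copy()     # (hist,)
    occupancy[0] = x0

    clamp_warned = False
    for i, age in enumerate(range(age_start, age_end)):
        # rewards on cycle-start membership, full-year accrual
        occ_alive = alive.sum(axis=0)
        if age >= M1_END_AGE or config.accrue_childhood_costs:
            disc_cost[i] = occ_alive @ cost_total[age] * df[age]
        if age >= qaly_start:
            disc_qaly[i] = occ_alive @ util[age] * df[age]
        # mortality: uniform in childhood, state/history-dependent from 18
        if age < M1_END_AGE:
            q = np.full((2, 3), qx[age])
        else:
            q = qx[age] * rr_cat[None, :] * rr_hist[:, None]
            if np.any(q > 1.0):
                if not clamp_warned:
                    logger.warning(
                        "adjusted death probability exceeded 1 at age %d (%s, %s); clamped",
                        age, sex.name, arm.value,
                    )
                    clamp_warned = True
                q = np.minimum(q, 1.0)
        dead += (alive * q).sum(axis=1)
        alive = alive * (1.0 - q)
        # BMI movement among survivors
        alive = alive @ A[age]
        # entering OW/OB flips the history flag from the next instant on
        alive[HIST_EVER, _OW] += alive[HIST_NEVER, _OW]
        alive[HIST_EVER, _OB] += alive[HIST_NEVER, _OB]
        alive[HIST_NEVER, _OW] = 0.0
        alive[HIST_NEVER, _OB] = 0.0
        occupancy[i + 1, :3] = alive[0]
        occupancy[i + 1, 3] = dead[0]
        occupancy[i + 1, 4:7] = alive[1]
        occupancy[i + 1, 7] = dead[1]

    trace = CohortTrace(
        arm=arm,
        sex=sex,
        ages=np.arange(age_start, age_end + 1),
        occupancy=occupancy,
        disc_cost=disc_cost,
        disc_qaly=disc_qaly,
    )
    trace.validate()
    return trace


def run_m1(
    params: ParameterSet, arm: Arm, sex: Sex, config: RunConfig
) -> tuple[CohortTrace, np.ndarray]:
    """Childhood model: ages 0..18.  Returns the trace and the age-18 hand-off."""
    if arm not in (Arm.LP, Arm.HP):
        raise ValueError(f"arm must be LP or HP, got {arm}")
    x0 = _initial_expanded(params.initial[sex])
    trace = _propagate(params, arm, sex, config, 0, M1_END_AGE, x0)
    handoff = trace.occupancy[-1].copy()
    return trace, handoff


def run_m2(
    params: ParameterSet, handoff: np.ndarray, sex: Sex, config: RunConfig, arm: Arm
) -> CohortTrace:
    """Adulthood model: from the age-18 hand-off to the horizon."""
    handoff = np.asarray(handoff, dtype=float)
    if handoff.shape != (N_EXPANDED,):
        raise ValueError(f"handoff must have {N_EXPANDED} entries")
    if abs(handoff.sum() - 1.0) > ROW_SUM_TOL:
        raise ValueError(f"handoff must sum to 1, got {handoff.sum():.12g}")
    return _propagate(params, arm, sex, config, M1_END_AGE, config.horizon_age, handoff)


def summarize_arm(traces: list[CohortTrace], config: RunConfig) -> ArmResult:
    """Fold contiguous traces (M1 then M2) into lifetime per-person totals."""
    if not traces:
        raise ValueError("no traces to summarize")
    traces = sorted(traces, key=lambda t: t.ages[0])
    for prev, nxt in zip(traces, traces[1:]):
        if prev.ages[-1] != nxt.ages[0]:
            raise ValueError(
                f"age gap between traces: {prev.ages[-1]} -> {nxt.ages[0]}"
            )

    lifetime_cost = 0.0
    lifetime_qaly = 0.0
    person_years_owob = 0.0
    life_expectancy = 0.0
    decade_costs = np.zeros(10)
    for trace in traces:
        lifetime_cost += trace.disc_cost.sum()
        lifetime_qaly += trace.disc_qaly.sum()
        cycle_ages = trace.ages[:-1]
        person_years_owob += trace.owob_mass[:-1].sum()
        life_expectancy += trace.alive_mass[:-1].sum()
        np.add.at(decade_costs, np.minimum(cycle_ages // 10, 9), trace.disc_cost)

    result = ArmResult(
        lifetime_cost_pp=float(lifetime_cost),
        lifetime_qaly_pp=float(lifetime_qaly),
        person_years_owob=float(person_years_owob),
        decade_costs=decade_costs,
        life_expectancy=float(life_expectancy),
    )
    result.validate(horizon=float(config.horizon_age))
    return result


def run_arm(
    params: ParameterSet, arm: Arm, sex: Sex, config: RunConfig
) -> tuple[ArmResult, list[CohortTrace]]:
    """Run M1 + M2 for one arm and sex and summarize."""
    m1, handoff = run_m1(params, arm, sex, config)
    m2 = run_m2(params, handoff, sex, config, arm)
    return summarize_arm([m1, m2], config), [m1, m2]


def mix_results(by_sex: dict[Sex, ArmResult], sex_mix: tuple[float, float]) -> ArmResult:
    """Sex-mix-weighted average of per-sex results."""
    w = {Sex.MALE: sex_mix[0], Sex.FEMALE: sex_mix[1]}
    mixed = ArmResult(
        lifetime_cost_pp=sum(w[s] * r.lifetime_cost_pp for s, r in by_sex.items()),
        lifetime_qaly_pp=sum(w[s] * r.lifetime_qaly_pp for s, r in by_sex.items()),
        person_years_owob=sum(w[s] * r.person_years_owob for s, r in by_sex.items()),
        decade_costs=sum(w[s] * r.decade_costs for s, r in by_sex.items()),
        life_expectancy=sum(w[s] * r.life_expectancy for s, r in by_sex.items()),
    )
    return mixed


def run_both_arms(
    params: ParameterSet, config: RunConfig, with_traces: bool = False
):
    """Deterministic base-case run: both arms, both sexes, plus mixed results.

    Returns ``(results, traces)`` where ``results[arm]['mixed'|Sex]`` holds
    :class:`ArmResult` objects and ``traces`` maps (arm, sex) to the trace
    list (empty dict unless ``with_traces``).
    """
    results: dict[Arm, dict] = {}
    traces: dict[tuple[Arm, Sex], list[CohortTrace]] = {}
    for arm in (Arm.LP, Arm.HP):
        by_sex: dict[Sex, ArmResult] = {}
        for sex in Sex:
            res, trc = run_arm(params, arm, sex, config)
            by_sex[sex] = res
            if with_traces:
                traces[(arm, sex)] = trc
        results[arm] = {**by_sex, "mixed": mix_results(by_sex, config.sex_mix)}
    return results, traces


def max_incidence_params(params: ParameterSet) -> ParameterSet:
    """Reference scenario for 'averted years': incidence forced maximal.

    Every alive row sends its full surviving mass to OBESE, so the cohort
    spends every possible life-year in an overweight/obese state.  Arm
    matrices and the intervention effect are neutralised.
    """
    ref = params.copy()
    forced = np.zeros((4, 4))
    forced[:3, BmiCategory.OBESE] = 1.0
    forced[BmiCategory.DEAD, BmiCategory.DEAD] = 1.0
    ref.transitions.common[:, :, :, :] = forced[None, None, :, :]
    ref.transitions.arm_specific = {}
    from .params import InterventionEffect, RelativeRisk  # local to avoid cycle noise

    ref.effect = InterventionEffect(
        rr_overweight=RelativeRisk(1.0, 1.0, 1.0),
        rr_obese=RelativeRisk(1.0, 1.0, 1.0),
        duration_years=0,
    )
    return ref
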