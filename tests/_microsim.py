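"""Independent individual-level microsimulation oracle.

Re-implements the cohort model's semantics at the person level with its own
code path: per-person annual category trajectories, history flags, uniform
childhood mortality, relative-risk-adjusted adult mortality, start-of-cycle
reward accrual and birth-referenced discounting.  Used to cross-validate
the deterministic cohort engine (means should agree within Monte Carlo
error).  Intentionally shares nothing with obesim.engine beyond the raw
parameter arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from obesim.params import Arm, ParameterSet, RunConfig, Sex

M1_END = 18
NORMAL, OW, OB = 0, 1, 2


@dataclass
class MicrosimResult:
    cost: np.ndarray        # discounted lifetime cost per person
    qaly: np.ndarray        # discounted lifetime QALYs per person
    owob_years: np.ndarray  # undiscounted years spent overweight/obese
    life_years: np.ndarray

    def mean_se(self, name: str) -> tuple[float, float]:
        arr = getattr(self, name)
        return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


def _arm_rows(params: ParameterSet, arm: Arm, sex: Sex) -> np.ndarray:
    """Annual alive-to-alive rows (N_AGES, 3, 3), renormalised past any death column.

    The LP intervention effect is re-derived here from first principles
    (multiply incidence, return the difference to the stay entry) rather
    than calling the engine's builder.
    """
    mats = params.transitions.common[sex].copy()
    explicit = params.transitions.arm_specific.get(arm)
    window = params.effect.duration_years
    for age in range(min(window, mats.shape[0])):
        if explicit is not None and age < explicit.shape[1]:
            mats[age] = explicit[sex, age]
        elif arm is Arm.LP:
            row = mats[age, NORMAL]
            ow = params.effect.rr_overweight.value * row[OW]
            ob = params.effect.rr_obese.value * row[OB]
            row[NORMAL] += (row[OW] - ow) + (row[OB] - ob)
            row[OW], row[OB] = ow, ob
    alive = mats[:, :3, :3]
    denom = 1.0 - mats[:, :3, 3]
    rows = np.divide(alive, denom[..., None], out=np.zeros_like(alive),
                     where=denom[..., None] > 0)
    return rows


def microsimulate(
    params: ParameterSet,
    arm: Arm,
    sex: Sex,
    config: RunConfig,
    n_persons: int,
    seed: int,
) -> MicrosimResult:
    rng = np.random.default_rng(seed)
    rows = _arm_rows(params, arm, sex)
    cum = rows.cumsum(axis=-1)
    qx = params.mortality.qx[sex]
    cost_total = params.costs.mean[sex].sum(axis=-1)  # (ages, 3)
    util = params.utilities.mean[sex]
    qaly_start = params.utilities.child_qaly_start_age
    rate = config.discount_rate
    rr_cat = np.array([1.0, params.mortality.rr_adult_ow.value,
                       params.mortality.rr_adult_ob.value])
    rr_hist = params.mortality.rr_childhood_history.value

    state = rng.choice(3, size=n_persons, p=params.initial[sex])
    hist = state != NORMAL
    alive = np.ones(n_persons, dtype=bool)
    cost = np.zeros(n_persons)
    qaly = np.zeros(n_persons)
    owob = np.zeros(n_persons)
    life = np.zeros(n_persons)

    for age in range(config.horizon_age):
        disc = (1.0 + rate) ** -age
        if alive.any():
            if age >= M1_END or config.accrue_childhood_costs:
                cost[alive] += cost_total[age, state[alive]] * disc
            if age >= qaly_start:
                qaly[alive] += util[age, state[alive]] * disc
            owob[alive] += (state[alive] != NORMAL)
            life[alive] += 1.0
        # mortality
        if age < M1_END:
            q = np.full(n_persons, qx[age])
        else:
            q = np.minimum(qx[age] * rr_cat[state] * np.where(hist, rr_hist, 1.0), 1.0)
        dies = alive & (rng.random(n_persons) < q)
        alive &= ~dies
        # BMI movement among survivors
        idx = np.flatnonzero(alive)
        if idx.size:
            u = rng.random(idx.size)
            c = cum[age, state[idx]]  # (k, 3)
            state[idx] = (u[:, None] > c).sum(axis=1)
            hist[idx] |= state[idx] != NORMAL
    return MicrosimResult(cost=cost, qaly=qaly, owob_years=owob, life_years=life)
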