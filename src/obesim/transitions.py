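"""Annual transition-probability derivation.

Two routes are supported: maximum-likelihood estimation from a longitudinal
category panel (annual visits), and conversion of multi-year interval
probabilities to annual ones under a constant-rate assumption, with
per-destination rate conversion and diagonal renormalisation.  The
intervention effect enters as relative risks multiplying the incidence
probabilities out of NORMAL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (
    ALIVE_CATEGORIES,
    ARM_AGE_WINDOW,
    N_AGES,
    ROW_SUM_TOL,
    Arm,
    BmiCategory,
    InterventionEffect,
    ParameterError,
    Sex,
    TransitionTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ("subject_id", "arm", "sex", "age", "category")


class PanelDataError(ParameterError):
    """Longitudinal panel input violates its contract."""


def annualize_two_state(p_interval: float, interval_years: int) -> float:
    """Convert a probability observed over ``interval_years`` to an annual one.

    Assumes a constant hazard over the interval, so the annual probability is
    ``1 - (1 - p)**(1/t)``; composing it ``t`` times reproduces ``p`` exactly.
    """
    p = float(p_interval)
    t = int(interval_years)
    if t < 1:
        raise ValueError(f"interval_years must be >= 1, got {interval_years}")
    if not (0.0 <= p < 1.0):
        raise ValueError(f"interval probability must be in [0, 1), got {p_interval}")
    return 1.0 - (1.0 - p) ** (1.0 / t)


@dataclass(frozen=True)
class IntervalTransition:
    """A from-state row of destination probabilities observed over a multi-year interval."""

    from_state: BmiCategory
    to_distribution: tuple[float, ...]  # over BmiCategory order
    interval_years: int
    age_at_start: int = 0
    sex: Sex = Sex.MALE

    def __post_init__(self) -> None:
        dist = np.asarray(self.to_distribution, dtype=float)
        if dist.shape != (4,):
            raise ValueError("to_distribution must have 4 entries (BmiCategory order)")
        if abs(dist.sum() - 1.0) > ROW_SUM_TOL:
            raise ValueError(f"to_distribution must sum to 1, got {dist.sum():.12g}")
        if (dist < 0).any() or (dist > 1).any():
            raise ValueError("to_distribution entries must lie in [0, 1]")
        if self.interval_years < 1:
            raise ValueError("interval_years must be >= 1")


def annualize_multistate(interval: IntervalTransition) -> np.ndarray:
    """Annualize a competing-risks interval row.

    Each off-diagonal interval probability is converted independently to a
    rate ``r = -ln(1 - p)/t`` and back to an annual probability
    ``1 - exp(-r)``; the residual mass is assigned to the stay (diagonal)
    entry.  If the off-diagonal annual probabilities exceed 1 in total, they
    are rescaled proportionally (a warning is logged).  Note that composing
    the annual row ``t`` times does not reproduce the interval row exactly
    under competing risks; the approximation error is a property of the
    method, not of this implementation.
    """
    row = np.asarray(interval.to_distribution, dtype=float)
    i = int(interval.from_state)
    t = interval.interval_years
    if np.any((row >= 1.0) & (np.arange(4) != i)):
        raise ValueError("off-diagonal interval probability of 1 has infinite rate")
    annual = np.zeros(4)
    off = [j for j in range(4) if j != i]
    for j in off:
        annual[j] = annualize_two_state(row[j], t)
    residual = 1.0 - annual[off].sum()
    if residual < 0.0:
        logger.warning(
            "annualized off-diagonal mass %.6g exceeds 1 for from_state=%s; "
            "rescaling proportionally", annual[off].sum(), interval.from_state.name,
        )
        annual[off] /= annual[off].sum()
        residual = 0.0
    annual[i] = residual
    return annual


def apply_relative_risk(row: np.ndarray, effect: InterventionEffect) -> np.ndarray:
    """Scale the incidence entries of a NORMAL row by the intervention RRs.

    ``p(NORMAL -> OVERWEIGHT)`` and ``p(NORMAL -> OBESE)`` are multiplied by
    their relative risks; the probability change is absorbed by the stay
    entry so the row sum and the death probability are preserved exactly.
    """
    row = np.asarray(row, dtype=float)
    if row.shape != (4,):
        raise ValueError("row must have 4 entries (BmiCategory order)")
    if abs(row.sum() - 1.0) > ROW_SUM_TOL:
        raise ValueError(f"row must be row-stochastic, sums to {row.sum():.12g}")
    new = row.copy()
    new_ow = effect.rr_overweight.value * row[BmiCategory.OVERWEIGHT]
    new_ob = effect.rr_obese.value * row[BmiCategory.OBESE]
    if new_ow > 1.0 or new_ob > 1.0:
        raise ValueError("relative risk times probability exceeds 1")
    shift = (row[BmiCategory.OVERWEIGHT] - new_ow) + (row[BmiCategory.OBESE] - new_ob)
    stay = row[BmiCategory.NORMAL] + shift
    if stay < 0.0 or stay > 1.0:
        raise ValueError(
            f"stay probability {stay:.6g} outside [0, 1] after applying relative risks"
        )
    new[BmiCategory.OVERWEIGHT] = new_ow
    new[BmiCategory.OBESE] = new_ob
    new[BmiCategory.NORMAL] = stay
    return new


@dataclass
class SmoothingConfig:
    """How to fill (age, sex) rows with no observed transitions.

    ``method='nearest'`` carries the nearest observed age's row for the same
    sex (and arm); ``method='uniform'`` spreads mass uniformly over the three
    living categories.  Death probability in estimated rows is the configured
    constant (panels of trial children record no deaths).
    """

    method: str = "nearest"
    death_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("nearest", "uniform"):
            raise ValueError(f"unknown smoothing method {self.method!r}")
        if not (0.0 <= self.death_probability < 1.0):
            raise ValueError("death_probability must be in [0, 1)")


@dataclass
class PanelEstimate:
    """Estimated transition rows plus bookkeeping of imputed cells."""

    entries: dict[tuple[Arm, Sex, int], np.ndarray]  # 4x4 matrices
    counts: dict[tuple[Arm, Sex, int], np.ndarray]   # 3x4 observed count rows
    filled: list[tuple[Arm, Sex, int, BmiCategory]] = field(default_factory=list)


def estimate_from_panel(
    panel: pd.DataFrame,
    smoothing: SmoothingConfig | None = None,
) -> PanelEstimate:
    """Maximum-likelihood annual transition rows from a longitudinal panel.

    The panel holds one row per (subject, age) visit with columns
    ``subject_id, arm, sex, age, category``.  For every pair of consecutive
    annual visits a transition is counted; each (arm, sex, age) row is the
    count-normalised distribution.  Rows with zero observed transitions are
    filled per the smoothing config and recorded in ``filled``.
    """
    smoothing = smoothing or SmoothingConfig()
    if panel is None or len(panel) == 0:
        raise PanelDataError("panel is empty")
    df = panel.copy()
    missing_cols = set(PANEL_COLUMNS) - set(df.columns)
    if missing_cols == {"arm"}:
        df["arm"] = Arm.COMMON.value
        missing_cols = set()
    if missing_cols:
        raise PanelDataError(f"panel missing columns: {sorted(missing_cols)}")

    df["arm"] = df["arm"].map(lambda v: Arm(str(v).strip().upper()))
    df["sex"] = df["sex"].map(lambda v: Sex[str(v).strip().upper()])
    df["category"] = df["category"].map(lambda v: BmiCategory[str(v).strip().upper()])
    df["age"] = df["age"].astype(int)

    counts: dict[tuple[Arm, Sex, int], np.ndarray] = {}
    # preserve visit order within subject so age regressions are detectable
    for (_, arm, sex), grp in df.groupby(["subject_id", "arm", "sex"], sort=True):
        arm = Arm(arm)
        sex = Sex(int(sex))
        ages = grp["age"].to_numpy()
        cats = grp["category"].to_numpy()
        if np.any(np.diff(ages) <= 0):
            raise PanelDataError(
                f"subject {grp['subject_id'].iloc[0]!r} has non-increasing ages"
            )
        for k in range(len(ages) - 1):
            if ages[k + 1] - ages[k] != 1:
                continue  # gap from a missed visit: no annual transition observed
            key = (arm, sex, int(ages[k]))
            mat = counts.setdefault(key, np.zeros((3, 4)))
            mat[int(cats[k]), int(cats[k + 1])] += 1.0

    if not counts:
        raise PanelDataError("panel contains no consecutive-age visit pairs")

    age_range = {
        (arm, sex) for arm, sex, _ in counts
    }
    ages_by_group: dict[tuple[Arm, Sex], list[int]] = {g: [] for g in age_range}
    for arm, sex, age in counts:
        ages_by_group[(arm, sex)].append(age)

    entries: dict[tuple[Arm, Sex, int], np.ndarray] = {}
    filled: list[tuple[Arm, Sex, int, BmiCategory]] = []
    q = smoothing.death_probability
    for (arm, sex), ages in ages_by_group.items():
        for age in sorted(ages):
            key = (arm, sex, age)
            cmat = counts[key]
            mat = np.zeros((4, 4))
            mat[BmiCategory.DEAD, BmiCategory.DEAD] = 1.0
            for frm in ALIVE_CATEGORIES:
                total = cmat[frm].sum()
                if total > 0:
                    alive_row = cmat[frm] / total
                    mat[frm] = (1.0 - q) * alive_row
                    mat[frm, BmiCategory.DEAD] += q
                else:
                    mat[frm] = _fill_row(counts, arm, sex, age, frm, smoothing)
                    filled.append((arm, sex, age, frm))
            entries[key] = mat
    if filled:
        logger.warning("estimate_from_panel imputed %d sparse rows", len(filled))
    return PanelEstimate(entries=entries, counts=counts, filled=filled)


def _fill_row(
    counts: dict,
    arm: Arm,
    sex: Sex,
    age: int,
    frm: BmiCategory,
    smoothing: SmoothingConfig,
) -> np.ndarray:
    q = smoothing.death_probability
    if smoothing.method == "nearest":
        candidates = sorted(
            (abs(a - age), a)
            for (c_arm, c_sex, a), mat in counts.items()
            if c_arm is arm and c_sex is sex and a != age and mat[frm].sum() > 0
        )
        for _, a in candidates:
            cmat = counts[(arm, sex, a)]
            alive_row = cmat[frm] / cmat[frm].sum()
            row = (1.0 - q) * alive_row
            row[BmiCategory.DEAD] += q
            return row
    # uniform fallback (also used when no donor age exists)
    row = np.full(4, (1.0 - q) / 3.0)
    row[BmiCategory.DEAD] = q
    return row


def panel_estimate_to_table(
    estimate: PanelEstimate,
    base: TransitionTable,
) -> TransitionTable:
    """Overlay panel-estimated arm rows (ages 0..5) onto a COMMON table."""
    table = TransitionTable(
        common=base.common.copy(),
        arm_specific={a: b.copy() for a, b in base.arm_specific.items()},
    )
    for (arm, sex, age), mat in estimate.entries.items():
        if arm is Arm.COMMON:
            if age >= N_AGES:
                raise ValidationError(f"estimated COMMON age {age} out of range")
            table.common[sex, age] = mat
        else:
            if age >= ARM_AGE_WINDOW:
                raise ValidationError(
                    f"arm-specific estimate at age {age} outside the 0..{ARM_AGE_WINDOW - 1} window"
                )
            block = table.arm_specific.setdefault(
                arm, base.common[:, :ARM_AGE_WINDOW].copy()
            )
            block[sex, age] = mat
    table.validate()
    return table
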