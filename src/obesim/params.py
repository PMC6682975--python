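"""Domain types, BMI-state classification, and parameter-table I/O.

The model works on four BMI categories (normal weight folds in underweight,
plus an absorbing dead state), annual one-year cycles from birth to a
configurable horizon, and two sexes.  All schedules are stored internally as
dense :mod:`numpy` arrays indexed ``[sex, age, ...]`` so that downstream
simulation and sensitivity analysis can operate vectorised; the on-disk
representation is a bundle of plain CSV tables (see :func:`load_parameters`).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Number of annual transition cycles; the matrix at age ``a`` governs the
#: move from age ``a`` to ``a + 1``, so cycles run over ages 0..99.
N_AGES = 100
#: Oldest age tracked (horizon of the lifetime model).
MAX_AGE = 100
#: Age at which the childhood model hands the cohort to the adulthood model.
M1_END_AGE = 18
#: Arm-specific transition rows may exist only for ages 0..5 (effect window).
ARM_AGE_WINDOW = 6
#: Lowest admissible utility value (worse-than-dead floor of the UK tariff).
MIN_UTILITY = -0.594

ROW_SUM_TOL = 1e-9


class BmiCategory(enum.IntEnum):
    """BMI state; ``NORMAL`` includes underweight, ``DEAD`` is absorbing."""

    NORMAL = 0
    OVERWEIGHT = 1
    OBESE = 2
    DEAD = 3


#: Living categories, in matrix order.
ALIVE_CATEGORIES = (BmiCategory.NORMAL, BmiCategory.OVERWEIGHT, BmiCategory.OBESE)


class Sex(enum.IntEnum):
    MALE = 0
    FEMALE = 1


class Arm(str, enum.Enum):
    """Strategy tag: lower-protein, higher-protein, or shared parameters."""

    LP = "LP"
    HP = "HP"
    COMMON = "COMMON"


class CostComponent(enum.IntEnum):
    DIRECT = 0
    INDIRECT = 1


class ParameterError(ValueError):
    """Base class for parameter-related failures."""


class MissingParameterError(ParameterError):
    """A required age/sex/state cell could not be resolved."""


class ValidationError(ParameterError):
    """A loaded table violates a structural invariant."""


class ConfigError(ValueError):
    """Run-configuration file is malformed."""


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_child(bmi_percentile: float) -> BmiCategory:
    """Classify a child's BMI percentile into a BMI category.

    Cutoffs are right-closed: normal weight up to and including the 90th
    percentile, overweight above the 90th up to and including the 97th,
    obese above the 97th.

    Parameters
    ----------
    bmi_percentile
        Reference percentile in ``[0, 100]``.
    """
    p = float(bmi_percentile)
    if not np.isfinite(p) or p < 0.0 or p > 100.0:
        raise ValueError(f"BMI percentile must be in [0, 100], got {bmi_percentile!r}")
    if p <= 90.0:
        return BmiCategory.NORMAL
    if p <= 97.0:
        return BmiCategory.OVERWEIGHT
    return BmiCategory.OBESE


def classify_adult(bmi: float) -> BmiCategory:
    """Classify an adult BMI (kg/m^2): <25 normal, [25, 30) overweight, >=30 obese."""
    b = float(bmi)
    if not np.isfinite(b) or b <= 0.0:
        raise ValueError(f"BMI must be positive and finite, got {bmi!r}")
    if b < 25.0:
        return BmiCategory.NORMAL
    if b < 30.0:
        return BmiCategory.OVERWEIGHT
    return BmiCategory.OBESE


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeSexKey:
    """Integer age (0..100) and sex; the lookup key for every schedule."""

    age: int
    sex: Sex

    def __post_init__(self) -> None:
        if not (0 <= int(self.age) <= MAX_AGE):
            raise ValueError(f"age must be in [0, {MAX_AGE}], got {self.age}")


@dataclass(frozen=True)
class RelativeRisk:
    """A point relative risk with its 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_low <= self.value <= self.ci_high):
            raise ValueError(
                f"require 0 < ci_low <= value <= ci_high, got "
                f"({self.value}, [{self.ci_low}, {self.ci_high}])"
            )


@dataclass(frozen=True)
class InterventionEffect:
    """Relative risks of becoming overweight/obese under the LP strategy.

    The effect multiplies the per-cycle incidence probabilities out of
    NORMAL for ``duration_years`` annual cycles starting at age 0.
    """

    rr_overweight: RelativeRisk
    rr_obese: RelativeRisk
    duration_years: int = ARM_AGE_WINDOW

    def __post_init__(self) -> None:
        if self.duration_years < 0:
            raise ValueError("duration_years must be >= 0")


@dataclass
class TransitionTable:
    """Row-stochastic 4x4 annual transition matrices per age, sex and arm.

    ``common`` covers ages 0..99 for both sexes; ``arm_specific`` optionally
    holds explicit LP/HP matrices for the effect window (ages 0..5).
    Matrix rows/columns follow ``BmiCategory`` order.
    """

    common: np.ndarray  # (2, N_AGES, 4, 4)
    arm_specific: dict[Arm, np.ndarray] = field(default_factory=dict)  # (2, 6, 4, 4)

    def validate(self) -> None:
        self._check_block(self.common, Arm.COMMON, n_ages=N_AGES)
        for arm, block in self.arm_specific.items():
            if arm not in (Arm.LP, Arm.HP):
                raise ValidationError(f"arm-specific block tagged {arm!r}; expected LP or HP")
            self._check_block(block, arm, n_ages=ARM_AGE_WINDOW)

    @staticmethod
    def _check_block(block: np.ndarray, arm: Arm, n_ages: int) -> None:
        if block.shape != (2, n_ages, 4, 4):
            raise ValidationError(
                f"{arm.value} transition block has shape {block.shape}, "
                f"expected (2, {n_ages}, 4, 4)"
            )
        if np.isnan(block).any():
            sex_i, age_i, row_i, _ = map(int, np.argwhere(np.isnan(block))[0])
            raise MissingParameterError(
                f"transition cell missing for age={age_i}, sex={Sex(sex_i).name}, "
                f"arm={arm.value}, from_state={BmiCategory(row_i).name}"
            )
        out_of_range = (block < 0) | (block > 1)
        if out_of_range.any():
            sex_i, age_i, row_i, col_i = map(int, np.argwhere(out_of_range)[0])
            raise ValidationError(
                f"transition probability outside [0, 1] "
                f"(value={block[sex_i, age_i, row_i, col_i]:.12g}) for age={age_i}, "
                f"sex={Sex(sex_i).name}, arm={arm.value}, "
                f"from_state={BmiCategory(row_i).name} -> {BmiCategory(col_i).name}"
            )
        sums = block.sum(axis=-1)
        bad = np.argwhere(np.abs(sums - 1.0) > ROW_SUM_TOL)
        if bad.size:
            sex_i, age_i, row_i = map(int, bad[0])
            raise ValidationError(
                f"transition row does not sum to 1 (sum={sums[tuple(bad[0])]:.12g}) "
                f"for age={age_i}, sex={Sex(sex_i).name}, arm={arm.value}, "
                f"from_state={BmiCategory(row_i).name}"
            )
        dead_rows = block[:, :, BmiCategory.DEAD, :]
        expected = np.zeros(4)
        expected[BmiCategory.DEAD] = 1.0
        if not np.allclose(dead_rows, expected, atol=ROW_SUM_TOL):
            raise ValidationError(f"{arm.value} DEAD row must be (0, 0, 0, 1)")

    def matrix(self, age: int, sex: Sex, arm: Arm = Arm.COMMON) -> np.ndarray:
        """Return the 4x4 matrix governing the transition from ``age`` to ``age+1``.

        Explicit arm-specific entries (ages 0..5) take precedence; otherwise
        the COMMON matrix is returned.  Note this is a *table* lookup — the
        LP intervention effect applied on top of COMMON rows lives in the
        engine, not here.
        """
        if not (0 <= age < N_AGES):
            raise MissingParameterError(
                f"no transition matrix for age={age} (valid range 0..{N_AGES - 1})"
            )
        if arm in self.arm_specific and age < ARM_AGE_WINDOW:
            return self.arm_specific[arm][sex, age]
        return self.common[sex, age]


@dataclass
class MortalityInputs:
    """Life-table death probabilities and mortality relative risks.

    ``qx[sex, age]`` is the annual probability of dying between ``age`` and
    ``age + 1``.  The adult relative risks apply to overweight/obese
    occupancy from age 18 on; the childhood-history RR applies to adults who
    were ever overweight/obese before 18.
    """

    qx: np.ndarray  # (2, MAX_AGE + 1)
    rr_adult_ow: RelativeRisk
    rr_adult_ob: RelativeRisk
    rr_childhood_history: RelativeRisk

    def validate(self) -> None:
        if self.qx.shape != (2, MAX_AGE + 1):
            raise ValidationError(f"qx has shape {self.qx.shape}, expected (2, {MAX_AGE + 1})")
        if np.isnan(self.qx).any():
            sex_i, age_i = map(int, np.argwhere(np.isnan(self.qx))[0])
            raise MissingParameterError(
                f"mortality qx missing for age={age_i}, sex={Sex(sex_i).name}"
            )
        if (self.qx < 0).any() or (self.qx > 1).any():
            raise ValidationError("qx values must lie in [0, 1]")

    def baseline_qx(self, key: AgeSexKey) -> float:
        return float(self.qx[key.sex, key.age])


@dataclass
class CostSchedule:
    """Annual direct/indirect costs (EUR, 2015 price level) per age, sex, state.

    ``mean`` and ``se`` are shaped ``(2, N_AGES, 3, 2)`` over
    (sex, age, alive category, cost component).  DEAD accrues nothing.
    """

    mean: np.ndarray
    se: np.ndarray

    def validate(self) -> None:
        shape = (2, N_AGES, 3, 2)
        for name, arr in (("mean", self.mean), ("se", self.se)):
            if arr.shape != shape:
                raise ValidationError(f"cost {name} has shape {arr.shape}, expected {shape}")
        if np.isnan(self.mean).any():
            sex_i, age_i, st_i, comp_i = map(int, np.argwhere(np.isnan(self.mean))[0])
            raise MissingParameterError(
                f"cost cell missing for age={age_i}, sex={Sex(sex_i).name}, "
                f"state={BmiCategory(st_i).name}, component={CostComponent(comp_i).name}"
            )
        if (self.mean < 0).any():
            raise ValidationError("costs must be non-negative")
        if (np.nan_to_num(self.se) < 0).any():
            raise ValidationError("cost standard errors must be non-negative")

    def annual_total(self, sex: Sex) -> np.ndarray:
        """Direct + indirect cost, shape (N_AGES, 3)."""
        return self.mean[sex].sum(axis=-1)


@dataclass
class UtilitySchedule:
    """EQ-5D-style utility indices per age, sex, alive state.

    Utilities below ``child_qaly_start_age`` are never accrued (quality of
    life is modelled for adolescents/adults only) and may be absent (NaN)
    in the table.
    """

    mean: np.ndarray  # (2, N_AGES, 3)
    se: np.ndarray
    child_qaly_start_age: int = M1_END_AGE

    def validate(self) -> None:
        shape = (2, N_AGES, 3)
        for name, arr in (("mean", self.mean), ("se", self.se)):
            if arr.shape != shape:
                raise ValidationError(f"utility {name} has shape {arr.shape}, expected {shape}")
        required = self.mean[:, self.child_qaly_start_age:, :]
        if np.isnan(required).any():
            sex_i, age_i, st_i = map(int, np.argwhere(np.isnan(required))[0])
            raise MissingParameterError(
                f"utility cell missing for age={age_i + self.child_qaly_start_age}, "
                f"sex={Sex(sex_i).name}, state={BmiCategory(st_i).name}"
            )
        if (required < MIN_UTILITY).any() or (required > 1.0).any():
            raise ValidationError(f"utilities must lie in [{MIN_UTILITY}, 1]")


@dataclass
class RunConfig:
    """Run-level configuration: economics, cohort and PSA settings."""

    discount_rate: float = 0.03
    wtp_grid: tuple[float, ...] = (0.0, 1000.0, 5000.0, 10000.0, 20000.0, 50000.0)
    psa_draws: int = 4000
    seed: int = 0
    formula_fed_share: float = 0.19
    birth_cohort_size: int = 700_000
    sex_mix: tuple[float, float] = (0.5, 0.5)  # (MALE, FEMALE)
    horizon_age: int = MAX_AGE
    accrue_childhood_costs: bool = True

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")
        grid = tuple(float(w) for w in self.wtp_grid)
        if any(w < 0 for w in grid) or list(grid) != sorted(grid):
            raise ConfigError("wtp_grid must be non-negative and sorted ascending")
        self.wtp_grid = grid
        if self.psa_draws < 1:
            raise ConfigError("psa_draws must be >= 1")
        if not (0.0 <= self.formula_fed_share <= 1.0):
            raise ConfigError("formula_fed_share must be in [0, 1]")
        if self.birth_cohort_size <= 0:
            raise ConfigError("birth_cohort_size must be positive")
        mix = tuple(float(s) for s in self.sex_mix)
        if len(mix) != 2 or abs(sum(mix) - 1.0) > ROW_SUM_TOL or any(s < 0 for s in mix):
            raise ConfigError("sex_mix must be two non-negative proportions summing to 1")
        self.sex_mix = mix
        if not (M1_END_AGE < self.horizon_age <= MAX_AGE):
            raise ConfigError(f"horizon_age must be in ({M1_END_AGE}, {MAX_AGE}]")

    _FIELDS = (
        "discount_rate", "wtp_grid", "psa_draws", "seed", "formula_fed_share",
        "birth_cohort_size", "sex_mix", "horizon_age", "accrue_childhood_costs",
    )

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        unknown = set(data) - set(cls._FIELDS)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "sex_mix" in kwargs and isinstance(kwargs["sex_mix"], Mapping):
            mix = {str(k).upper(): float(v) for k, v in kwargs["sex_mix"].items()}
            try:
                kwargs["sex_mix"] = (mix["MALE"], mix["FEMALE"])
            except KeyError as exc:
                raise ConfigError(f"sex_mix missing key {exc}") from exc
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigError(f"configuration file {path} must hold a mapping")
        return cls.from_mapping(data)

    def to_mapping(self) -> dict:
        return {
            "discount_rate": self.discount_rate,
            "wtp_grid": list(self.wtp_grid),
            "psa_draws": self.psa_draws,
            "seed": self.seed,
            "formula_fed_share": self.formula_fed_share,
            "birth_cohort_size": self.birth_cohort_size,
            "sex_mix": {"MALE": self.sex_mix[0], "FEMALE": self.sex_mix[1]},
            "horizon_age": self.horizon_age,
            "accrue_childhood_costs": self.accrue_childhood_costs,
        }

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_mapping()
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class ParameterSet:
    """The complete calibrated model input.

    ``initial`` is the age-0 distribution over the three living categories,
    shaped ``(2, 3)`` per sex; it must sum to 1 per sex.
    """

    transitions: TransitionTable
    effect: InterventionEffect
    mortality: MortalityInputs
    costs: CostSchedule
    utilities: UtilitySchedule
    initial: np.ndarray
    validation: list[str] = field(default_factory=list)

    def validate(self) -> None:
        self.transitions.validate()
        self.mortality.validate()
        self.costs.validate()
        self.utilities.validate()
        if self.initial.shape != (2, 3):
            raise ValidationError(
                f"initial distribution has shape {self.initial.shape}, expected (2, 3)"
            )
        if (self.initial < 0).any():
            raise ValidationError("initial distribution shares must be non-negative")
        sums = self.initial.sum(axis=-1)
        if np.abs(sums - 1.0).max() > ROW_SUM_TOL:
            raise ValidationError(f"initial distribution must sum to 1 per sex, got {sums}")

    def copy(self) -> "ParameterSet":
        """Deep copy (fresh arrays) suitable for per-draw PSA mutation."""
        return ParameterSet(
            transitions=TransitionTable(
                common=self.transitions.common.copy(),
                arm_specific={a: b.copy() for a, b in self.transitions.arm_specific.items()},
            ),
            effect=self.effect,
            mortality=MortalityInputs(
                qx=self.mortality.qx.copy(),
                rr_adult_ow=self.mortality.rr_adult_ow,
                rr_adult_ob=self.mortality.rr_adult_ob,
                rr_childhood_history=self.mortality.rr_childhood_history,
            ),
            costs=CostSchedule(mean=self.costs.mean.copy(), se=self.costs.se.copy()),
            utilities=UtilitySchedule(
                mean=self.utilities.mean.copy(),
                se=self.utilities.se.copy(),
                child_qaly_start_age=self.utilities.child_qaly_start_age,
            ),
            initial=self.initial.copy(),
            validation=list(self.validation),
        )


# ---------------------------------------------------------------------------
# CSV bundle I/O
# ---------------------------------------------------------------------------

BUNDLE_FILES = (
    "transitions.csv",
    "mortality.csv",
    "mortality_rr.csv",
    "costs.csv",
    "utilities.csv",
    "intervention.csv",
    "initial.csv",
)

_RR_CONTEXTS = ("ADULT_OVERWEIGHT", "ADULT_OBESE", "CHILDHOOD_HISTORY")


def _read_csv(directory: Path, name: str) -> pd.DataFrame:
    path = directory / name
    if not path.exists():
        raise MissingParameterError(f"required parameter table not found: {path}")
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # surfaced with path context
        raise ParameterError(f"could not parse {path}: {exc}") from exc


def _parse_enum(df: pd.DataFrame, column: str, enum_cls, table: str):
    try:
        return df[column].map(lambda v: enum_cls[str(v).strip().upper()])
    except KeyError as exc:
        raise ValidationError(f"{table}: unknown {column} value {exc}") from exc


def load_parameters(directory: str | Path) -> ParameterSet:
    """Load and validate a full CSV parameter bundle.

    Expects the seven tables listed in :data:`BUNDLE_FILES` under
    ``directory``.  Every required age/sex/state cell must be present; a
    missing cell raises :class:`MissingParameterError` naming it, and any
    structural violation (row sums, ranges) raises :class:`ValidationError`.
    """
    directory = Path(directory)
    report: list[str] = []

    # transitions
    tdf = _read_csv(directory, "transitions.csv")
    tdf = tdf.assign(
        sex=_parse_enum(tdf, "sex", Sex, "transitions.csv"),
        arm=_parse_enum(tdf, "arm", Arm, "transitions.csv"),
        from_state=_parse_enum(tdf, "from_state", BmiCategory, "transitions.csv"),
        to_state=_parse_enum(tdf, "to_state", BmiCategory, "transitions.csv"),
    )
    common = np.full((2, N_AGES, 4, 4), np.nan)
    arm_specific: dict[Arm, np.ndarray] = {}
    for row in tdf.itertuples(index=False):
        age = int(row.age)
        if row.arm is Arm.COMMON:
            if not (0 <= age < N_AGES):
                raise ValidationError(f"transitions.csv: COMMON age {age} out of range 0..{N_AGES - 1}")
            common[row.sex, age, row.from_state, row.to_state] = float(row.prob)
        else:
            if not (0 <= age < ARM_AGE_WINDOW):
                raise ValidationError(
                    f"transitions.csv: arm-specific entries allowed only for ages "
                    f"0..{ARM_AGE_WINDOW - 1}, got age {age} for arm {row.arm.value}"
                )
            block = arm_specific.setdefault(row.arm, np.full((2, ARM_AGE_WINDOW, 4, 4), np.nan))
            block[row.sex, age, row.from_state, row.to_state] = float(row.prob)
    transitions = TransitionTable(common=common, arm_specific=arm_specific)

    # mortality
    mdf = _read_csv(directory, "mortality.csv")
    mdf = mdf.assign(sex=_parse_enum(mdf, "sex", Sex, "mortality.csv"))
    qx = np.full((2, MAX_AGE + 1), np.nan)
    for row in mdf.itertuples(index=False):
        age = int(row.age)
        if not (0 <= age <= MAX_AGE):
            raise ValidationError(f"mortality.csv: age {age} out of range 0..{MAX_AGE}")
        qx[row.sex, age] = float(row.qx)

    rdf = _read_csv(directory, "mortality_rr.csv").set_index("context")
    rrs = {}
    for context in _RR_CONTEXTS:
        if context not in rdf.index:
            raise MissingParameterError(f"mortality_rr.csv: missing context {context}")
        rec = rdf.loc[context]
        rrs[context] = RelativeRisk(float(rec["rr"]), float(rec["ci_low"]), float(rec["ci_high"]))
    mortality = MortalityInputs(
        qx=qx,
        rr_adult_ow=rrs["ADULT_OVERWEIGHT"],
        rr_adult_ob=rrs["ADULT_OBESE"],
        rr_childhood_history=rrs["CHILDHOOD_HISTORY"],
    )

    # costs
    cdf = _read_csv(directory, "costs.csv")
    cdf = cdf.assign(
        sex=_parse_enum(cdf, "sex", Sex, "costs.csv"),
        state=_parse_enum(cdf, "state", BmiCategory, "costs.csv"),
        component=_parse_enum(cdf, "component", CostComponent, "costs.csv"),
    )
    cost_mean = np.full((2, N_AGES, 3, 2), np.nan)
    cost_se = np.zeros((2, N_AGES, 3, 2))
    for row in cdf.itertuples(index=False):
        if row.state is BmiCategory.DEAD:
            raise ValidationError("costs.csv: DEAD must not carry cost entries")
        cost_mean[row.sex, int(row.age), row.state, row.component] = float(row.mean)
        cost_se[row.sex, int(row.age), row.state, row.component] = float(row.se)
    costs = CostSchedule(mean=cost_mean, se=cost_se)

    # utilities
    udf = _read_csv(directory, "utilities.csv")
    udf = udf.assign(
        sex=_parse_enum(udf, "sex", Sex, "utilities.csv"),
        state=_parse_enum(udf, "state", BmiCategory, "utilities.csv"),
    )
    util_mean = np.full((2, N_AGES, 3), np.nan)
    util_se = np.zeros((2, N_AGES, 3))
    for row in udf.itertuples(index=False):
        if row.state is BmiCategory.DEAD:
            raise ValidationError("utilities.csv: DEAD must not carry utility entries")
        util_mean[row.sex, int(row.age), row.state] = float(row.mean)
        util_se[row.sex, int(row.age), row.state] = float(row.se)
    utilities = UtilitySchedule(mean=util_mean, se=util_se)

    # intervention effect
    idf = _read_csv(directory, "intervention.csv").set_index("outcome")
    effect_rrs = {}
    duration = ARM_AGE_WINDOW
    for outcome in ("OVERWEIGHT", "OBESE"):
        if outcome not in idf.index:
            raise MissingParameterError(f"intervention.csv: missing outcome {outcome}")
        rec = idf.loc[outcome]
        effect_rrs[outcome] = RelativeRisk(
            float(rec["rr"]), float(rec["ci_low"]), float(rec["ci_high"])
        )
        duration = int(rec["duration_years"])
    effect = InterventionEffect(
        rr_overweight=effect_rrs["OVERWEIGHT"],
        rr_obese=effect_rrs["OBESE"],
        duration_years=duration,
    )

    # initial distribution
    ndf = _read_csv(directory, "initial.csv")
    ndf = ndf.assign(
        sex=_parse_enum(ndf, "sex", Sex, "initial.csv"),
        state=_parse_enum(ndf, "state", BmiCategory, "initial.csv"),
    )
    initial = np.full((2, 3), np.nan)
    for row in ndf.itertuples(index=False):
        if row.state is BmiCategory.DEAD:
            raise ValidationError("initial.csv: newborns cannot start DEAD")
        initial[row.sex, row.state] = float(row.share)
    if np.isnan(initial).any():
        sex_i, st_i = map(int, np.argwhere(np.isnan(initial))[0])
        raise MissingParameterError(
            f"initial.csv: missing share for sex={Sex(sex_i).name}, "
            f"state={BmiCategory(st_i).name}"
        )

    ps = ParameterSet(
        transitions=transitions,
        effect=effect,
        mortality=mortality,
        costs=costs,
        utilities=utilities,
        initial=initial,
        validation=report,
    )
    ps.validate()
    for line in report:
        logger.warning(line)
    logger.info("loaded parameter bundle from %s (%d tables)", directory, len(BUNDLE_FILES))
    return ps


def write_parameters(ps: ParameterSet, directory: str | Path) -> dict[str, Path]:
    """Write a ParameterSet as the CSV bundle read by :func:`load_parameters`.

    Floats are written at full precision, so a load/write round trip is
    numerically exact.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    trows = []
    blocks = [(Arm.COMMON, ps.transitions.common, N_AGES)]
    blocks += [(arm, blk, ARM_AGE_WINDOW) for arm, blk in ps.transitions.arm_specific.items()]
    for arm, block, n_ages in blocks:
        for sex in Sex:
            for age in range(n_ages):
                for frm in BmiCategory:
                    for to in BmiCategory:
                        trows.append(
                            (age, sex.name, arm.value, frm.name, to.name,
                             repr(float(block[sex, age, frm, to])))
                        )
    paths["transitions.csv"] = _write_rows(
        directory / "transitions.csv",
        ("age", "sex", "arm", "from_state", "to_state", "prob"), trows)

    mrows = [
        (age, sex.name, repr(float(ps.mortality.qx[sex, age])))
        for sex in Sex for age in range(MAX_AGE + 1)
    ]
    paths["mortality.csv"] = _write_rows(directory / "mortality.csv", ("age", "sex", "qx"), mrows)

    rr_map = {
        "ADULT_OVERWEIGHT": ps.mortality.rr_adult_ow,
        "ADULT_OBESE": ps.mortality.rr_adult_ob,
        "CHILDHOOD_HISTORY": ps.mortality.rr_childhood_history,
    }
    rrows = [(ctx, repr(rr.value), repr(rr.ci_low), repr(rr.ci_high)) for ctx, rr in rr_map.items()]
    paths["mortality_rr.csv"] = _write_rows(
        directory / "mortality_rr.csv", ("context", "rr", "ci_low", "ci_high"), rrows)

    crows = []
    for sex in Sex:
        for age in range(N_AGES):
            for state in ALIVE_CATEGORIES:
                for comp in CostComponent:
                    crows.append(
                        (age, sex.name, state.name, comp.name,
                         repr(float(ps.costs.mean[sex, age, state, comp])),
                         repr(float(ps.costs.se[sex, age, state, comp])))
                    )
    paths["costs.csv"] = _write_rows(
        directory / "costs.csv", ("age", "sex", "state", "component", "mean", "se"), crows)

    urows = []
    for sex in Sex:
        for age in range(N_AGES):
            for state in ALIVE_CATEGORIES:
                mean = ps.utilities.mean[sex, age, state]
                if np.isnan(mean):
                    continue  # ages below the QALY start may be absent
                urows.append(
                    (age, sex.name, state.name, repr(float(mean)),
                     repr(float(ps.utilities.se[sex, age, state])))
                )
    paths["utilities.csv"] = _write_rows(
        directory / "utilities.csv", ("age", "sex", "state", "mean", "se"), urows)

    irows = [
        ("OVERWEIGHT", repr(ps.effect.rr_overweight.value), repr(ps.effect.rr_overweight.ci_low),
         repr(ps.effect.rr_overweight.ci_high), ps.effect.duration_years),
        ("OBESE", repr(ps.effect.rr_obese.value), repr(ps.effect.rr_obese.ci_low),
         repr(ps.effect.rr_obese.ci_high), ps.effect.duration_years),
    ]
    paths["intervention.csv"] = _write_rows(
        directory / "intervention.csv",
        ("outcome", "rr", "ci_low", "ci_high", "duration_years"), irows)

    nrows = [
        (sex.name, state.name, repr(float(ps.initial[sex, state])))
        for sex in Sex for state in ALIVE_CATEGORIES
    ]
    paths["initial.csv"] = _write_rows(directory / "initial.csv", ("sex", "state", "share"), nrows)
    return paths


def _write_rows(path: Path, header: tuple, rows: list) -> Path:
    lines = [",".join(header)]
    lines += [",".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
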