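"""Probabilistic sensitivity analysis.

Parameter cells are resampled per draw from their assigned distributions —
log-normal for relative risks (parameterised from the 95% CI), gamma for
costs (method of moments from mean and SE), uniform when only a range is
known, FIXED as a degenerate fallback.  Both arms share every common draw,
so with the intervention relative risks held at 1 each draw produces
exactly zero increments (common-random-numbers contract).  Draw ``i`` uses
RNG substream ``i`` spawned from the master seed, so results do not depend
on execution order.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import yaml

from .engine import ArmResult, run_both_arms
from .params import (
    Arm,
    BmiCategory,
    CostComponent,
    InterventionEffect,
    MissingParameterError,
    MortalityInputs,
    ParameterSet,
    RelativeRisk,
    RunConfig,
    Sex,
)

logger = logging.getLogger(__name__)

Z_975 = 1.959964  # standard normal 97.5% quantile


class DistributionKind(str, enum.Enum):
    LOGNORMAL = "LOGNORMAL"
    GAMMA = "GAMMA"
    UNIFORM = "UNIFORM"
    FIXED = "FIXED"


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling assignment for one ParameterSet cell (or a wildcard group).

    Supported targets::

        intervention.rr_overweight      intervention.rr_obese
        mortality.rr_adult_ow           mortality.rr_adult_ob
        mortality.rr_childhood_history
        costs.*                         (per-cell gamma from stored mean/se)
        costs[age,SEX,STATE,COMPONENT]  (one cell)

    ``p1``/``p2`` carry kind-specific parameters: LOGNORMAL uses the cell's
    own CI unless (ci_low, ci_high) are given; GAMMA uses (se,) overriding
    the stored one; UNIFORM uses (low, high); FIXED uses (value,) or the
    current cell value.
    """

    target: str
    kind: DistributionKind
    p1: float | None = None
    p2: float | None = None


def lognormal_from_ci(point: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) with median ``point`` and 95% CI width from the bounds."""
    if not (0.0 < ci_low <= point <= ci_high):
        raise ValueError(
            f"require 0 < ci_low <= point <= ci_high, got ({point}, [{ci_low}, {ci_high}])"
        )
    mu = np.log(point)
    sigma = (np.log(ci_high) - np.log(ci_low)) / (2.0 * Z_975)
    return float(mu), float(sigma)


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments (shape, scale); ``se = 0`` degenerates to a point mass."""
    if mean <= 0.0:
        raise ValueError(f"mean must be positive, got {mean}")
    if se < 0.0:
        raise ValueError(f"se must be >= 0, got {se}")
    if se == 0.0:
        return float("inf"), 0.0  # point mass sentinel; samplers special-case it
    shape = mean ** 2 / se ** 2
    scale = se ** 2 / mean
    return float(shape), float(scale)


def _sample_lognormal(rng: np.random.Generator, point: float, lo: float, hi: float) -> float:
    mu, sigma = lognormal_from_ci(point, lo, hi)
    if sigma == 0.0:
        return float(point)
    return float(rng.lognormal(mean=mu, sigma=sigma))


def _sample_gamma(rng, mean, se):
    if se == 0.0:
        return float(mean)
    shape, scale = gamma_from_moments(mean, se)
    return float(rng.gamma(shape, scale))


_COST_CELL_RE = re.compile(r"^costs\[(\d+),\s*(\w+),\s*(\w+),\s*(\w+)\]$")

_SCALAR_TARGETS = (
    "intervention.rr_overweight",
    "intervention.rr_obese",
    "mortality.rr_adult_ow",
    "mortality.rr_adult_ob",
    "mortality.rr_childhood_history",
)


def validate_specs(params: ParameterSet, specs: list[DistributionSpec]) -> None:
    """Fail fast (before any simulation) on specs targeting missing cells."""
    for spec in specs:
        if spec.target in _SCALAR_TARGETS or spec.target == "costs.*":
            continue
        m = _COST_CELL_RE.match(spec.target)
        if not m:
            raise MissingParameterError(f"unknown PSA target {spec.target!r}")
        age = int(m.group(1))
        try:
            Sex[m.group(2).upper()]
            BmiCategory[m.group(3).upper()]
            CostComponent[m.group(4).upper()]
        except KeyError as exc:
            raise MissingParameterError(f"PSA target {spec.target!r}: bad key {exc}") from exc
        if not (0 <= age < params.costs.mean.shape[1]):
            raise MissingParameterError(f"PSA target {spec.target!r}: age out of range")


def _scalar_rr(params: ParameterSet, target: str) -> RelativeRisk:
    if target == "intervention.rr_overweight":
        return params.effect.rr_overweight
    if target == "intervention.rr_obese":
        return params.effect.rr_obese
    if target == "mortality.rr_adult_ow":
        return params.mortality.rr_adult_ow
    if target == "mortality.rr_adult_ob":
        return params.mortality.rr_adult_ob
    if target == "mortality.rr_childhood_history":
        return params.mortality.rr_childhood_history
    raise MissingParameterError(f"unknown scalar target {target!r}")


def _set_scalar_rr(params: ParameterSet, target: str, value: float) -> None:
    rr = RelativeRisk(value, min(value, value), max(value, value))
    if target == "intervention.rr_overweight":
        params.effect = InterventionEffect(
            rr_overweight=rr, rr_obese=params.effect.rr_obese,
            duration_years=params.effect.duration_years,
        )
    elif target == "intervention.rr_obese":
        params.effect = InterventionEffect(
            rr_overweight=params.effect.rr_overweight, rr_obese=rr,
            duration_years=params.effect.duration_years,
        )
    elif target == "mortality.rr_adult_ow":
        params.mortality = MortalityInputs(
            qx=params.mortality.qx, rr_adult_ow=rr,
            rr_adult_ob=params.mortality.rr_adult_ob,
            rr_childhood_history=params.mortality.rr_childhood_history,
        )
    elif target == "mortality.rr_adult_ob":
        params.mortality = MortalityInputs(
            qx=params.mortality.qx, rr_adult_ow=params.mortality.rr_adult_ow,
            rr_adult_ob=rr,
            rr_childhood_history=params.mortality.rr_childhood_history,
        )
    elif target == "mortality.rr_childhood_history":
        params.mortality = MortalityInputs(
            qx=params.mortality.qx, rr_adult_ow=params.mortality.rr_adult_ow,
            rr_adult_ob=params.mortality.rr_adult_ob, rr_childhood_history=rr,
        )
    else:
        raise MissingParameterError(f"unknown scalar target {target!r}")


def apply_spec(params: ParameterSet, spec: DistributionSpec, rng: np.random.Generator) -> None:
    """Sample one spec and write the result into ``params`` in place."""
    kind = spec.kind
    if spec.target == "costs.*":
        if kind is DistributionKind.FIXED:
            return
        if kind is not DistributionKind.GAMMA:
            raise ValueError("costs.* wildcard supports GAMMA or FIXED only")
        mean = params.costs.mean
        se = params.costs.se
        with np.errstate(divide="ignore", invalid="ignore"):
            shape = np.where(se > 0, mean ** 2 / np.maximum(se, 1e-300) ** 2, 1.0)
            scale = np.where(se > 0, se ** 2 / np.maximum(mean, 1e-300), 0.0)
        draws = np.where(
            (se > 0) & (mean > 0), rng.gamma(np.maximum(shape, 1e-12), 1.0) * scale, mean
        )
        params.costs.mean = draws
        return

    m = _COST_CELL_RE.match(spec.target)
    if m:
        age = int(m.group(1))
        sex = Sex[m.group(2).upper()]
        state = BmiCategory[m.group(3).upper()]
        comp = CostComponent[m.group(4).upper()]
        mean = float(params.costs.mean[sex, age, state, comp])
        if kind is DistributionKind.GAMMA:
            se = float(spec.p1) if spec.p1 is not None else float(params.costs.se[sex, age, state, comp])
            params.costs.mean[sex, age, state, comp] = _sample_gamma(rng, mean, se)
        elif kind is DistributionKind.UNIFORM:
            lo = float(spec.p1) if spec.p1 is not None else mean
            hi = float(spec.p2) if spec.p2 is not None else mean
            if lo > hi:
                raise ValueError(f"UNIFORM requires low <= high for {spec.target}")
            params.costs.mean[sex, age, state, comp] = (
                mean if lo == hi else float(rng.uniform(lo, hi))
            )
        elif kind is DistributionKind.FIXED:
            if spec.p1 is not None:
                params.costs.mean[sex, age, state, comp] = float(spec.p1)
        else:
            raise ValueError(f"{kind.value} not supported for cost cells")
        return

    # scalar relative-risk targets
    rr = _scalar_rr(params, spec.target)
    if kind is DistributionKind.FIXED:
        value = float(spec.p1) if spec.p1 is not None else rr.value
    elif kind is DistributionKind.LOGNORMAL:
        lo = float(spec.p1) if spec.p1 is not None else rr.ci_low
        hi = float(spec.p2) if spec.p2 is not None else rr.ci_high
        value = _sample_lognormal(rng, rr.value, lo, hi)
    elif kind is DistributionKind.UNIFORM:
        lo = float(spec.p1) if spec.p1 is not None else rr.ci_low
        hi = float(spec.p2) if spec.p2 is not None else rr.ci_high
        if lo > hi:
            raise ValueError(f"UNIFORM requires low <= high for {spec.target}")
        value = rr.value if lo == hi else float(rng.uniform(lo, hi))
    else:
        raise ValueError(f"{kind.value} not supported for relative-risk targets")
    _set_scalar_rr(params, spec.target, value)


@dataclass
class PSAResult:
    """Per-draw arm results (sex-mixed) and empirical summaries."""

    draws: list[tuple[ArmResult, ArmResult]]  # (LP, HP) per draw
    summaries: dict[str, dict[str, float]]
    seed: int
    n_draws: int

    def deltas(self) -> list[tuple[float, float]]:
        """Per-draw (delta_cost, delta_qaly), LP minus HP."""
        return [
            (lp.lifetime_cost_pp - hp.lifetime_cost_pp,
             lp.lifetime_qaly_pp - hp.lifetime_qaly_pp)
            for lp, hp in self.draws
        ]


_SUMMARY_QUANTITIES = {
    "lifetime_cost_lp": lambda lp, hp: lp.lifetime_cost_pp,
    "lifetime_cost_hp": lambda lp, hp: hp.lifetime_cost_pp,
    "lifetime_qaly_lp": lambda lp, hp: lp.lifetime_qaly_pp,
    "lifetime_qaly_hp": lambda lp, hp: hp.lifetime_qaly_pp,
    "delta_cost": lambda lp, hp: lp.lifetime_cost_pp - hp.lifetime_cost_pp,
    "delta_qaly": lambda lp, hp: lp.lifetime_qaly_pp - hp.lifetime_qaly_pp,
    "person_years_owob_lp": lambda lp, hp: lp.person_years_owob,
    "person_years_owob_hp": lambda lp, hp: hp.person_years_owob,
}


def summarize_draws(draws: list[tuple[ArmResult, ArmResult]]) -> dict[str, dict[str, float]]:
    """Mean and empirical 2.5/97.5 percentiles (linear interpolation, type 7)."""
    out: dict[str, dict[str, float]] = {}
    for name, fn in _SUMMARY_QUANTITIES.items():
        values = np.array([fn(lp, hp) for lp, hp in draws])
        out[name] = {
            "mean": float(values.mean()),
            "p2.5": float(np.percentile(values, 2.5)),
            "p97.5": float(np.percentile(values, 97.5)),
        }
    return out


def run_psa(
    params: ParameterSet,
    specs: list[DistributionSpec],
    config: RunConfig,
    n_draws: int | None = None,
) -> PSAResult:
    """Run the full PSA: ``n_draws`` samples, both arms per draw, summaries.

    Reproducible given ``config.seed``; draw ``i`` always consumes substream
    ``i`` of the master seed sequence regardless of any parallel execution.
    """
    n = int(n_draws if n_draws is not None else config.psa_draws)
    if n < 1:
        raise ValueError("n_draws must be >= 1")
    validate_specs(params, specs)
    streams = np.random.SeedSequence(config.seed).spawn(n)
    draws: list[tuple[ArmResult, ArmResult]] = []
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        drawn = params.copy()
        for spec in specs:
            apply_spec(drawn, spec, rng)
        results, _ = run_both_arms(drawn, config)
        draws.append((results[Arm.LP]["mixed"], results[Arm.HP]["mixed"]))
    result = PSAResult(
        draws=draws, summaries=summarize_draws(draws), seed=config.seed, n_draws=n
    )
    logger.info("PSA complete: %d draws, seed %d", n, config.seed)
    return result


# ---------------------------------------------------------------------------
# spec file I/O
# ---------------------------------------------------------------------------

def load_specs(path) -> list[DistributionSpec]:
    """Read DistributionSpecs from a YAML list of {target, kind, p1, p2}."""
    data = yaml.safe_load(open(path).read())
    if not isinstance(data, list):
        raise ValueError(f"spec file {path} must hold a list")
    specs = []
    for entry in data:
        specs.append(
            DistributionSpec(
                target=str(entry["target"]),
                kind=DistributionKind(str(entry["kind"]).upper()),
                p1=None if entry.get("p1") is None else float(entry["p1"]),
                p2=None if entry.get("p2") is None else float(entry["p2"]),
            )
        )
    return specs


def write_specs(specs: list[DistributionSpec], path) -> None:
    data = [
        {"target": s.target, "kind": s.kind.value, "p1": s.p1, "p2": s.p2} for s in specs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def default_specs() -> list[DistributionSpec]:
    """The distribution assignments used by the base analysis.

    Relative risks are log-normal around their confidence intervals; every
    cost cell is gamma with its stored mean/SE.
    """
    return [
        DistributionSpec("intervention.rr_overweight", DistributionKind.LOGNORMAL),
        DistributionSpec("intervention.rr_obese", DistributionKind.LOGNORMAL),
        DistributionSpec("mortality.rr_adult_ow", DistributionKind.LOGNORMAL),
        DistributionSpec("mortality.rr_adult_ob", DistributionKind.LOGNORMAL),
        DistributionSpec("mortality.rr_childhood_history", DistributionKind.LOGNORMAL),
        DistributionSpec("costs.*", DistributionKind.GAMMA),
    ]
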