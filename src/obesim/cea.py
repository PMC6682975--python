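"""Incremental cost-effectiveness layer.

All increments follow the LP-minus-HP sign convention: a cheaper LP arm has
a negative ``delta_cost``, so the net monetary benefit at willingness-to-pay
zero equals the per-person saving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import ArmResult
from .params import RunConfig, Sex

#: |delta QALY| below which the ICER is flagged undefined.
ICER_QALY_EPS = 1e-12


@dataclass
class Incremental:
    delta_cost: float
    delta_qaly: float
    icer: float | None        # None when |delta_qaly| < ICER_QALY_EPS
    dominant: bool            # LP cheaper and more effective


@dataclass
class CEAResult:
    """Incremental comparison of the LP and HP arms."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominant: bool
    nmb_curve: dict[float, float]
    per_sex: dict[str, Incremental] = field(default_factory=dict)
    averted_years_diff: float = 0.0
    population_savings: float = 0.0
    ceac: dict[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "dominant": self.dominant,
            "nmb_curve": {str(w): v for w, v in self.nmb_curve.items()},
            "per_sex": {
                s: {
                    "delta_cost": inc.delta_cost,
                    "delta_qaly": inc.delta_qaly,
                    "icer": inc.icer,
                    "dominant": inc.dominant,
                }
                for s, inc in self.per_sex.items()
            },
            "averted_years_diff": self.averted_years_diff,
            "population_savings": self.population_savings,
            "ceac": None if self.ceac is None else {str(w): p for w, p in self.ceac.items()},
        }


def incremental(lp: ArmResult, hp: ArmResult) -> Incremental:
    """LP-minus-HP cost and QALY increments with ICER and dominance flag."""
    delta_cost = lp.lifetime_cost_pp - hp.lifetime_cost_pp
    delta_qaly = lp.lifetime_qaly_pp - hp.lifetime_qaly_pp
    if abs(delta_qaly) < ICER_QALY_EPS:
        icer = None
    else:
        icer = delta_cost / delta_qaly
    dominant = delta_cost < 0.0 and delta_qaly > 0.0
    return Incremental(delta_cost=delta_cost, delta_qaly=delta_qaly, icer=icer, dominant=dominant)


def nmb(delta_qaly: float, delta_cost: float, wtp: float) -> float:
    """Net monetary benefit: health gain valued at WTP minus incremental cost."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    if not (math.isfinite(delta_qaly) and math.isfinite(delta_cost)):
        raise ValueError("increments must be finite")
    return delta_qaly * wtp - delta_cost


def ceac(
    deltas: list[tuple[float, float]], wtp_grid: tuple[float, ...] | list[float]
) -> dict[float, float]:
    """Probability of cost-effectiveness per WTP from PSA draw increments.

    ``deltas`` holds per-draw ``(delta_cost, delta_qaly)`` pairs.  A draw
    counts as cost-effective when its NMB is strictly positive (ties count
    against, which keeps the estimate deterministic).
    """
    if not deltas:
        raise ValueError("no PSA draws supplied")
    arr = np.asarray(deltas, dtype=float)
    out: dict[float, float] = {}
    for wtp in wtp_grid:
        nmbs = arr[:, 1] * float(wtp) - arr[:, 0]
        out[float(wtp)] = float(np.mean(nmbs > 0.0))
    return out


def averted_years(
    lp: ArmResult, hp: ArmResult, reference: ArmResult
) -> tuple[float, float, float]:
    """Averted years with overweight/obesity per arm relative to a reference.

    The per-arm values depend on the reference scenario; their difference
    (``averted_lp - averted_hp``) cancels the reference and equals the
    HP-minus-LP difference in person-years spent overweight/obese.
    """
    if reference is None:
        raise ValueError("a reference ArmResult is required")
    averted_lp = reference.person_years_owob - lp.person_years_owob
    averted_hp = reference.person_years_owob - hp.person_years_owob
    return averted_lp, averted_hp, averted_lp - averted_hp


def population_savings(
    savings_pp: float, formula_fed_share: float, cohort_size: float
) -> float:
    """Scale a per-person saving to the formula-fed share of a birth cohort."""
    if savings_pp < 0 or not (0.0 <= formula_fed_share <= 1.0) or cohort_size < 0:
        raise ValueError("inputs must be non-negative with share in [0, 1]")
    return savings_pp * formula_fed_share * cohort_size


def evaluate(
    results: dict,
    config: RunConfig,
    psa_deltas: list[tuple[float, float]] | None = None,
    reference_results: dict | None = None,
) -> CEAResult:
    """Build the full CEA report from deterministic (and optional PSA) output.

    ``results`` is the mapping produced by :func:`obesim.engine.run_both_arms`;
    ``reference_results`` (same shape) supplies the averted-years baseline —
    when absent only the reference-free difference is reported.
    """
    from .params import Arm  # deferred: avoid import noise at module top

    lp_mixed = results[Arm.LP]["mixed"]
    hp_mixed = results[Arm.HP]["mixed"]
    inc = incremental(lp_mixed, hp_mixed)
    curve = {
        float(w): nmb(inc.delta_qaly, inc.delta_cost, float(w)) for w in config.wtp_grid
    }
    per_sex = {
        sex.name: incremental(results[Arm.LP][sex], results[Arm.HP][sex]) for sex in Sex
    }
    diff = hp_mixed.person_years_owob - lp_mixed.person_years_owob
    if reference_results is not None:
        ref_mixed = reference_results[Arm.LP]["mixed"]
        _, _, diff = averted_years(lp_mixed, hp_mixed, ref_mixed)
    savings_pp = max(0.0, -inc.delta_cost)
    pop = population_savings(savings_pp, config.formula_fed_share, config.birth_cohort_size)
    curve_ceac = ceac(psa_deltas, config.wtp_grid) if psa_deltas else None
    return CEAResult(
        delta_cost=inc.delta_cost,
        delta_qaly=inc.delta_qaly,
        icer=inc.icer,
        dominant=inc.dominant,
        nmb_curve=curve,
        per_sex=per_sex,
        averted_years_diff=diff,
        population_savings=pop,
        ceac=curve_ceac,
    )
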