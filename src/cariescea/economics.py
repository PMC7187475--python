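"""Discounted costs, DMFT-time, QALYs and ICERs from cohort traces.

Conventions
-----------
* **Event costing** — a state's unit cost is charged once, on the incident
  mass entering it (so each re-entry into RepeatFilling re-incurs the
  filling fee), multiplied by the number of molars.
* **QALY and DMFT** — per-cycle occupancy weighted by the state's utility
  (resp. DMFT flag) times the cycle length.  Both are per-molar averages:
  all eight molars are exchangeable so the average equals a single trace.
  DMFT is additionally scaled by a configurable aggregation factor
  (default 1, i.e. discounted DMFT-state-years per molar).
* **Intervention cost** — the varnish fee accrues every cycle per surviving
  individual, independent of tooth state.
* **Discounting** — annual-step factors.  The default ``year_end`` timing
  discounts everything accrued in model year *y* by (1+r)^-(y+1) (ordinary
  annuity, the convention of a spreadsheet NPV column); ``year_start`` uses
  (1+r)^-y and ``cycle_end`` compounds per cycle.  There is no half-cycle
  correction by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .cohort_engine import CohortTrace
from .model_core import DEATH_STATE, HealthStateSpec, ModelParams

__all__ = [
    "discount_factor",
    "cycle_discount_factors",
    "ArmResult",
    "IcerResult",
    "accumulate_arm",
    "compute_icer",
]

EffectMeasure = Literal["prevented_dmft", "qaly_gained"]


def discount_factor(rate: float, time: float) -> float:
    """Annual-step discount factor (1 + rate)^(-floor(time in years))."""
    if rate < 0:
        raise ValueError(f"negative discount rate {rate}")
    if time < 0:
        raise ValueError(f"negative time {time}")
    return (1.0 + rate) ** (-math.floor(time))


def cycle_discount_factors(
    rate: float,
    n_cycles: int,
    cycle_length: float,
    timing: str = "year_end",
) -> np.ndarray:
    """Discount factor applied to amounts accrued during each cycle k.

    Cycle k covers model time [k*cl, (k+1)*cl).  ``year_start`` discounts by
    the factor at the start of the year containing the cycle;``year_end``
    shifts one further year (payments fall due at the end of each model
    year); ``cycle_end`` compounds continuously to the cycle's end time.
    """
    k = np.arange(n_cycles)
    t = k * cycle_length
    if timing == "year_start":
        return np.array([discount_factor(rate, ti) for ti in t])
    if timing == "year_end":
        return np.array([discount_factor(rate, ti) for ti in t]) / (1.0 + rate)
    if timing == "cycle_end":
        return (1.0 + rate) ** (-(k + 1) * cycle_length)
    raise ValueError(f"unknown discount timing {timing!r}")


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals for one arm: cost (AUD), DMFT-time, QALYs.

    ``total_cost`` = treatment (event) cost over all molars + intervention
    cost when applicable; ``dmft`` and ``qaly`` are per-molar discounted
    state-time aggregates (the eight molars are exchangeable).
    """

    arm_label: str
    total_cost: float
    treatment_cost: float
    intervention_cost: float
    dmft: float
    qaly: float
    discount_rate: float

    def __post_init__(self) -> None:
        if min(self.total_cost, self.dmft, self.qaly) < -1e-9:
            raise ValueError("arm totals must be non-negative")


def accumulate_arm(
    trace: CohortTrace,
    states: Sequence[HealthStateSpec],
    params: ModelParams,
    include_intervention_cost: bool = False,
    applications_per_cycle: int = 1,
    arm_label: str | None = None,
    discount_rate: float | None = None,
) -> ArmResult:
    """Fold a cohort trace into discounted cost, DMFT-time and QALY totals."""
    if trace.n_states != len(states):
        raise ValueError(
            f"trace has {trace.n_states} states, specs have {len(states)}"
        )
    rate = params.discount_rate if discount_rate is None else discount_rate
    n = trace.n_cycles
    cl = params.cycle_length
    df = cycle_discount_factors(rate, n, cl, params.discount_timing)

    costs = np.array([s.unit_cost for s in states])
    utils = np.array([s.utility for s in states])
    flags = np.array([float(s.dmft_flag) for s in states])

    occ = trace.occupancy
    occ_eff = 0.5 * (occ[:-1] + occ[1:]) if params.half_cycle_correction else occ[:-1]

    # events on transition k -> k+1 are accrued in cycle k
    treatment = float(df @ (trace.entries[1:] @ costs)) * params.n_molars
    qaly = float(df @ (occ_eff @ utils)) * cl
    dmft = float(df @ (occ_eff @ flags)) * cl * params.dmft_aggregation_factor

    intervention = 0.0
    if include_intervention_cost:
        alive = 1.0 - occ[:-1, DEATH_STATE] if trace.n_states > DEATH_STATE else np.ones(n)
        intervention = float(
            df @ alive
        ) * params.intervention_cost_per_cycle * applications_per_cycle

    return ArmResult(
        arm_label=arm_label
        or ("intervention" if include_intervention_cost else "current_practice"),
        total_cost=treatment + intervention,
        treatment_cost=treatment,
        intervention_cost=intervention,
        dmft=dmft,
        qaly=qaly,
        discount_rate=rate,
    )


@dataclass(frozen=True)
class IcerResult:
    """Incremental cost-effectiveness of intervention vs comparator.

    ``quadrant`` places (delta_effect, delta_cost) on the cost-effectiveness
    plane (NE = more effective and more costly).  ``verdict`` compares the
    ratio against the willingness-to-pay threshold: NE is cost-effective
    when ICER <= threshold, SW when ICER >= threshold; SE dominates, NW is
    dominated.  ``undefined`` flags a zero effect difference (no ratio).
    """

    effect_measure: str
    delta_cost: float
    delta_effect: float
    icer: float  # nan when undefined
    quadrant: str
    verdict: str
    undefined: bool
    threshold: float


_EFFECT_EPS = 1e-12


def compute_icer(
    base: ArmResult,
    intervention: ArmResult,
    effect: EffectMeasure = "qaly_gained",
    threshold: float | None = None,
) -> IcerResult:
    """ICER of ``intervention`` against ``base`` for one effect measure.

    prevented_dmft counts DMFT averted (base - intervention); qaly_gained
    counts QALYs added (intervention - base).  Both are oriented so a
    beneficial intervention has positive delta_effect.
    """
    if threshold is None:
        threshold = ModelParams().wtp_threshold
    delta_cost = intervention.total_cost - base.total_cost
    if effect == "prevented_dmft":
        delta_effect = base.dmft - intervention.dmft
    elif effect == "qaly_gained":
        delta_effect = intervention.qaly - base.qaly
    else:
        raise ValueError(f"unknown effect measure {effect!r}")

    if abs(delta_effect) < _EFFECT_EPS:
        return IcerResult(
            effect_measure=effect,
            delta_cost=delta_cost,
            delta_effect=delta_effect,
            icer=math.nan,
            quadrant="N" if delta_cost > 0 else ("S" if delta_cost < 0 else "origin"),
            verdict="undefined",
            undefined=True,
            threshold=threshold,
        )

    icer = delta_cost / delta_effect
    ns = "N" if delta_cost >= 0 else "S"
    ew = "E" if delta_effect > 0 else "W"
    quadrant = ns + ew
    if quadrant == "SE":
        verdict = "dominant"
    elif quadrant == "NW":
        verdict = "dominated"
    elif quadrant == "NE":
        verdict = "cost_effective" if icer <= threshold else "not_cost_effective"
    else:  # SW: forgoing effect, saving money
        verdict = "cost_effective" if icer >= threshold else "not_cost_effective"
    return IcerResult(
        effect_measure=effect,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        quadrant=quadrant,
        verdict=verdict,
        undefined=False,
        threshold=threshold,
    )
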