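"""Synthetic transition matrices, life tables, and output-space calibration.

The transition probabilities behind the published comparator arm were
estimated from private insurer claims data and were never printed, so this
module synthesises age-indexed matrices with the structure the analysis
assumes: a one-way clinical pathway

    NoDisease -> EnamelDecay -> DentineDecay -> Filling
              -> {RepeatFilling, RootCanal, Extraction}
              -> {Crown, Bridge, Implant}

with constant per-cycle base rates (caries incidence assumed constant over
age), an optional multiplicative age gradient on onset, and a Gompertz-style
background-mortality life table.  :func:`calibrate` then tunes a handful of
generator rates so that the *comparator arm's* discounted totals (cost,
DMFT-time, QALY) match given target values — calibration is to model
outputs, never to the intervention arm, whose results must emerge from the
prevented-fraction mechanism alone.

Everything here is deterministic given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .cohort_engine import run_cohort
from .economics import accumulate_arm
from .model_core import (
    DEATH_STATE,
    N_STATES,
    ModelConfig,
    state_index,
)
from .transitions import (
    LifeTable,
    TransitionModel,
    augment_with_mortality,
    validate_transition_model,
)

__all__ = [
    "GeneratorParams",
    "CalibrationTarget",
    "CalibrationResult",
    "default_generator_params",
    "base_case_targets",
    "full_reference_targets",
    "generate_transition_model",
    "generate_life_table",
    "comparator_outputs",
    "calibrate",
]

#: Default random/reproducibility seed for all synthetic artefacts.
DEFAULT_SEED = 20190827

# Transition edges of the restorative pathway, keyed by readable rate names.
_EDGES: dict[str, tuple[str, str]] = {
    "enamel_to_dentine": ("EnamelDecay", "DentineDecay"),
    "dentine_to_filling": ("DentineDecay", "Filling"),
    "filling_to_repeat": ("Filling", "RepeatFilling"),
    "filling_to_root_canal": ("Filling", "RootCanal"),
    "filling_to_extraction": ("Filling", "Extraction"),
    "repeat_to_root_canal": ("RepeatFilling", "RootCanal"),
    "repeat_to_extraction": ("RepeatFilling", "Extraction"),
    "root_canal_to_crown": ("RootCanal", "Crown"),
    "root_canal_to_extraction": ("RootCanal", "Extraction"),
    "crown_to_extraction": ("Crown", "Extraction"),
    "extraction_to_bridge": ("Extraction", "Bridge"),
    "extraction_to_implant": ("Extraction", "Implant"),
    "bridge_to_implant": ("Bridge", "Implant"),
}

#: Rates treated as one scaled group by the calibration (everything past
#: the first restoration).
DOWNSTREAM_KEYS: tuple[str, ...] = (
    "filling_to_root_canal",
    "filling_to_extraction",
    "repeat_to_root_canal",
    "repeat_to_extraction",
    "root_canal_to_crown",
    "root_canal_to_extraction",
    "crown_to_extraction",
    "extraction_to_bridge",
    "extraction_to_implant",
    "bridge_to_implant",
)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic transition/mortality generator.

    ``caries_onset_rate`` is the per-cycle NoDisease -> EnamelDecay
    probability at the start age; ``age_gradient`` multiplies it per decade
    of age (1.0 = constant incidence, the default assumption).
    ``progression_rates`` are per-cycle probabilities along the pathway
    edges.  Mortality is Gompertz-like: annual q doubles every
    ``mortality_doubling_years`` from ``mortality_baseline`` at the start
    age.
    """

    caries_onset_rate: float
    progression_rates: Mapping[str, float]
    age_gradient: float = 1.0
    mortality_baseline: float = 2.0e-4
    mortality_doubling_years: float = 9.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not 0.0 <= self.caries_onset_rate <= 1.0:
            raise ValueError("caries_onset_rate outside [0, 1]")
        unknown = set(self.progression_rates) - set(_EDGES)
        if unknown:
            raise ValueError(f"unknown progression rate(s) {sorted(unknown)}")
        for k, v in self.progression_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"progression rate {k} = {v} outside [0, 1]")
        if self.mortality_baseline < 0 or self.mortality_doubling_years <= 0:
            raise ValueError("invalid mortality parameters")

    def rate(self, key: str) -> float:
        return float(self.progression_rates.get(key, 0.0))

    def replace(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorParams":
        d = dict(d)
        rates = dict(d.pop("progression_rates", {}))
        return cls(progression_rates=rates, **d)

    def to_dict(self) -> dict:
        return {
            "caries_onset_rate": float(self.caries_onset_rate),
            "progression_rates": {
                k: float(v) for k, v in self.progression_rates.items()
            },
            "age_gradient": float(self.age_gradient),
            "mortality_baseline": float(self.mortality_baseline),
            "mortality_doubling_years": float(self.mortality_doubling_years),
            "seed": int(self.seed),
        }


def default_generator_params() -> GeneratorParams:
    """Generator parameters of the packaged base case.

    These are the output of running :func:`calibrate` against the
    comparator-arm reference totals at all three discount rates
    (:func:`full_reference_targets`), rounded to four significant figures
    and frozen here so every run starts from the same base case.  They
    reproduce the nine reference totals to within about 1.5% relative
    error each.
    """
    return GeneratorParams(
        caries_onset_rate=0.1503,
        progression_rates={
            "enamel_to_dentine": 0.2958,
            "dentine_to_filling": 0.6000,
            "filling_to_repeat": 0.0001,
            "filling_to_root_canal": 0.002927,
            "filling_to_extraction": 0.001463,
            "repeat_to_root_canal": 0.005853,
            "repeat_to_extraction": 0.002927,
            "root_canal_to_crown": 0.01463,
            "root_canal_to_extraction": 0.007316,
            "crown_to_extraction": 0.007316,
            "extraction_to_bridge": 0.001463,
            "extraction_to_implant": 0.001463,
            "bridge_to_implant": 0.0007316,
        },
        mortality_baseline=2.018e-4,
        mortality_doubling_years=9.0,
    )


def generate_transition_model(
    gp: GeneratorParams, start_age: int = 15, max_age: int = 75
) -> TransitionModel:
    """Build age-indexed 11-state matrices from generator rates.

    Each age band's matrix places the pathway rates off-diagonal and the
    remaining mass on the self-transition; the Death row is absorbing and
    no mass enters Death (mortality is added separately).  Raises if rates
    exceed a row's budget (the self-transition would go negative).
    """
    matrices: dict[int, np.ndarray] = {}
    for age in range(start_age, max_age + 1):
        m = np.zeros((N_STATES, N_STATES))
        onset = gp.caries_onset_rate * gp.age_gradient ** ((age - start_age) / 10.0)
        if onset > 1.0:
            raise ValueError(f"age {age}: onset rate {onset} exceeds 1")
        m[state_index("NoDisease"), state_index("EnamelDecay")] = onset
        for key, (src, dst) in _EDGES.items():
            m[state_index(src), state_index(dst)] = gp.rate(key)
        for i in range(DEATH_STATE):
            off = m[i].sum()
            if off > 1.0 + 1e-12:
                raise ValueError(
                    f"age {age}: outgoing rates from state {i} sum to {off} > 1"
                )
            m[i, i] = 1.0 - off
        m[DEATH_STATE, DEATH_STATE] = 1.0
        matrices[age] = m
    return validate_transition_model(TransitionModel(matrices))


def generate_life_table(
    baseline: float,
    doubling_years: float = 10.0,
    start_age: int = 15,
    end_age: int = 85,
    seed: int | None = None,
    cap: float = 0.99,
) -> LifeTable:
    """Gompertz-style life table: q(a) = baseline * 2^((a - start)/doubling).

    q is non-decreasing in age and capped below 1.  Deterministic; ``seed``
    is accepted for interface symmetry with the matrix generator.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if doubling_years <= 0:
        raise ValueError("doubling_years must be > 0")
    q = {
        age: min(baseline * 2.0 ** ((age - start_age) / doubling_years), cap)
        for age in range(start_age, end_age + 1)
    }
    if q[end_age] >= 1.0:
        raise ValueError("life table reaches q = 1 before the horizon end")
    return LifeTable(q)


def _mortality_model(gp: GeneratorParams, core: ModelConfig) -> TransitionModel:
    p = core.params
    tooth = generate_transition_model(
        gp, start_age=int(p.start_age), max_age=min(int(p.end_age) - 10, 75)
    )
    life = generate_life_table(
        gp.mortality_baseline,
        gp.mortality_doubling_years,
        start_age=int(p.start_age),
        end_age=int(p.end_age),
        seed=gp.seed,
    )
    return augment_with_mortality(tooth, life, p.cycle_length, end_age=int(p.end_age))


def comparator_outputs(
    gp: GeneratorParams,
    core: ModelConfig,
    discount_rates: Sequence[float] = (0.05,),
) -> dict[float, dict[str, float]]:
    """Comparator-arm discounted totals per discount rate for a parameter set."""
    model = _mortality_model(gp, core)
    trace = run_cohort(model, core.initial_distribution, core.params)
    out: dict[float, dict[str, float]] = {}
    for r in discount_rates:
        arm = accumulate_arm(
            trace, core.states, core.params, include_intervention_cost=False,
            discount_rate=r,
        )
        out[r] = {
            "comparator_cost": arm.total_cost,
            "comparator_dmft": arm.dmft,
            "comparator_qaly": arm.qaly,
        }
    return out


@dataclass(frozen=True)
class CalibrationTarget:
    """One comparator-arm output total to match, at a given discount rate."""

    quantity: str  # comparator_cost | comparator_dmft | comparator_qaly
    value: float
    discount_rate: float = 0.05
    tolerance: float = 0.10  # relative

    def __post_init__(self) -> None:
        if self.quantity not in (
            "comparator_cost",
            "comparator_dmft",
            "comparator_qaly",
        ):
            raise ValueError(f"unknown target quantity {self.quantity!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def base_case_targets(tolerance: float = 0.10) -> list[CalibrationTarget]:
    """Reference comparator totals at 5%/yr: cost 2303, DMFT 15.52, QALY 14.74."""
    return [
        CalibrationTarget("comparator_cost", 2303.0, 0.05, tolerance),
        CalibrationTarget("comparator_dmft", 15.52, 0.05, tolerance),
        CalibrationTarget("comparator_qaly", 14.74, 0.05, tolerance),
    ]


def full_reference_targets(tolerance: float = 0.10) -> list[CalibrationTarget]:
    """Reference comparator totals at all three discount rates.

    Adding the undiscounted and 3.5% columns pins the whole time path of
    the comparator arm, not just its 5%-discounted summary, which keeps the
    calibrated rates in a clinically sensible regime.
    """
    return base_case_targets(tolerance) + [
        CalibrationTarget("comparator_cost", 2969.0, 0.035, tolerance),
        CalibrationTarget("comparator_dmft", 21.49, 0.035, tolerance),
        CalibrationTarget("comparator_qaly", 19.25, 0.035, tolerance),
        CalibrationTarget("comparator_cost", 6810.0, 0.0, tolerance),
        CalibrationTarget("comparator_dmft", 59.41, 0.0, tolerance),
        CalibrationTarget("comparator_qaly", 47.45, 0.0, tolerance),
    ]


@dataclass
class CalibrationResult:
    params: GeneratorParams
    errors: dict[str, float]  # per-target relative error (keyed quantity@rate)
    objective: float
    success: bool
    n_evaluations: int
    message: str = ""

    @property
    def max_error(self) -> float:
        return max(self.errors.values()) if self.errors else 0.0


# Free parameters explored by the calibration search (log scale): caries
# onset, enamel->dentine, dentine->filling, filling->repeat, a common
# multiplier on all downstream restorative rates, and the mortality
# baseline.  The bounds keep every rate in a clinically plausible band
# (per-cycle probabilities well below 1; annual q15 between 5e-5 and
# 1.5e-3); they are part of the calibration design, not tuned per run.
_FREE = ("caries_onset_rate", "enamel_to_dentine", "dentine_to_filling",
         "filling_to_repeat", "downstream_scale", "mortality_baseline")
_FREE_UPPER = np.log([0.5, 0.5, 0.6, 0.25, 20.0, 1.5e-3])
_FREE_LOWER = np.log([1e-4, 1e-4, 1e-4, 1e-4, 1e-3, 5e-5])


def _apply_free(gp0: GeneratorParams, x: np.ndarray) -> GeneratorParams:
    onset, en_dn, dn_fi, fi_rf, scale, mort = np.exp(x)
    rates = dict(gp0.progression_rates)
    rates["enamel_to_dentine"] = en_dn
    rates["dentine_to_filling"] = dn_fi
    rates["filling_to_repeat"] = fi_rf
    for k in DOWNSTREAM_KEYS:
        rates[k] = gp0.rate(k) * scale
    return gp0.replace(
        caries_onset_rate=onset,
        progression_rates=rates,
        mortality_baseline=float(mort),
    )


def _free_vector(gp: GeneratorParams) -> np.ndarray:
    return np.log(
        [
            gp.caries_onset_rate,
            gp.rate("enamel_to_dentine"),
            gp.rate("dentine_to_filling"),
            gp.rate("filling_to_repeat"),
            1.0,
            gp.mortality_baseline,
        ]
    )


def calibrate(
    gp0: GeneratorParams,
    targets: Sequence[CalibrationTarget],
    core: ModelConfig,
    max_iter: int = 4000,
    seed: int | None = None,
) -> CalibrationResult:
    """Derivative-free search matching comparator totals to targets.

    Minimises the sum of squared relative errors over the targets with
    bounded Nelder-Mead (one restart) on the log of six free parameters:
    caries onset, enamel->dentine, dentine->filling, filling->repeat, a
    common downstream-restorative scale, and the mortality baseline.
    ``max_iter`` caps total objective evaluations.  Deterministic given the
    start point; ``seed`` is kept for interface symmetry.  Returns
    best-found parameters with per-target relative errors; ``success`` is
    True when every error is within its target's tolerance.
    """
    if not targets:
        return CalibrationResult(
            params=gp0, errors={}, objective=0.0, success=True,
            n_evaluations=0, message="no targets; parameters unchanged",
        )
    rates = sorted({t.discount_rate for t in targets})
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        if np.any(x > _FREE_UPPER) or np.any(x < _FREE_LOWER):
            return 1e6
        try:
            gp = _apply_free(gp0, x)
            outs = comparator_outputs(gp, core, discount_rates=rates)
        except ValueError:
            return 1e6
        err = 0.0
        for t in targets:
            got = outs[t.discount_rate][t.quantity]
            err += ((got - t.value) / t.value) ** 2
        return err

    # staged Nelder-Mead: restart from the incumbent (recovers from simplex
    # collapse) and once from a deterministic off-incumbent point (escapes
    # shallow local minima); keep the best point seen
    x0 = np.clip(_free_vector(gp0), _FREE_LOWER, _FREE_UPPER)
    opts = {"maxfev": max_iter // 4, "xatol": 1e-5, "fatol": 1e-12}
    x_best, f_best = x0, objective(x0)
    starts = [x0, None, "perturb", None]
    for start in starts:
        if start is None:
            start = x_best
        elif isinstance(start, str):
            start = np.clip(x_best + 0.3, _FREE_LOWER, _FREE_UPPER)
        res = optimize.minimize(
            objective, start, method="Nelder-Mead", options=opts
        )
        if res.fun < f_best:
            x_best, f_best = res.x, res.fun
    best = _apply_free(gp0, x_best)
    outs = comparator_outputs(best, core, discount_rates=rates)
    errors = {
        f"{t.quantity}@{t.discount_rate:g}": abs(
            outs[t.discount_rate][t.quantity] - t.value
        )
        / abs(t.value)
        for t in targets
    }
    success = all(
        errors[f"{t.quantity}@{t.discount_rate:g}"] <= t.tolerance for t in targets
    )
    return CalibrationResult(
        params=best,
        errors=errors,
        objective=float(res.fun),
        success=success,
        n_evaluations=n_eval,
        message="" if success else "calibration did not reach all tolerances",
    )
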