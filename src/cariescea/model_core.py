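"""Fixed model structure and scalar parameters for the fluoride-varnish CEA.

The decision problem is a Markov cohort model of dental caries progression in
eight permanent first/second molars, followed in 6-month cycles from age 15
to age 85 (140 cycles).  Each molar occupies one of ten tooth health states;
an explicit eleventh absorbing ``Death`` state carries background mortality.
This module holds the canonical state order, the per-state unit costs,
utility weights and DMFT flags, the scalar model parameters, and the initial
state distribution of the cohort, together with a YAML config reader/writer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "STATE_NAMES",
    "TOOTH_STATE_NAMES",
    "DEATH_STATE",
    "N_STATES",
    "state_index",
    "ConfigError",
    "HealthStateSpec",
    "ModelParams",
    "InitialDistribution",
    "ModelConfig",
    "default_states",
    "default_params",
    "default_initial_distribution",
    "default_config",
    "load_config",
    "write_config",
]

#: Canonical state order shared by every module.  Indices 0..9 are tooth
#: states (in order of clinical progression); index 10 is the absorbing
#: Death state.
STATE_NAMES: tuple[str, ...] = (
    "NoDisease",
    "EnamelDecay",
    "DentineDecay",
    "Filling",
    "RepeatFilling",
    "RootCanal",
    "Crown",
    "Extraction",
    "Bridge",
    "Implant",
    "Death",
)

TOOTH_STATE_NAMES: tuple[str, ...] = STATE_NAMES[:-1]
DEATH_STATE: int = 10
N_STATES: int = len(STATE_NAMES)

_STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}


def state_index(name: str) -> int:
    """Return the canonical index of a state name (raises ConfigError)."""
    try:
        return _STATE_INDEX[name]
    except KeyError:
        raise ConfigError("state", f"unknown state name {name!r}") from None


class ConfigError(ValueError):
    """Configuration problem; ``field`` names the offending entry."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class HealthStateSpec:
    """One tooth health state: cost on entry, utility weight, DMFT flag.

    ``unit_cost`` is the AUD cost incurred once, when a molar *enters* the
    state (an incident procedure such as placing a filling); no ongoing
    background cost accrues while occupying a state.  ``utility`` is the
    per-year quality-of-life weight in [0, 1].  ``dmft_flag`` marks states
    that count toward the decayed/missing/filled (DMFT) index.
    """

    name: str
    unit_cost: float
    utility: float
    dmft_flag: int

    def __post_init__(self) -> None:
        if self.name not in _STATE_INDEX:
            raise ConfigError("states.name", f"unknown state {self.name!r}")
        if not 0.0 <= self.utility <= 1.0:
            raise ConfigError(
                f"states.{self.name}.utility",
                f"utility {self.utility} outside [0, 1]",
            )
        if self.unit_cost < 0:
            raise ConfigError(
                f"states.{self.name}.unit_cost", "unit cost must be >= 0"
            )
        if self.dmft_flag not in (0, 1):
            raise ConfigError(
                f"states.{self.name}.dmft_flag", "DMFT flag must be 0 or 1"
            )
        if self.name == "Death" and (
            self.unit_cost != 0 or self.utility != 0 or self.dmft_flag != 0
        ):
            raise ConfigError(
                "states.Death", "Death must have zero cost, utility and DMFT flag"
            )


# AUD unit costs (2014 fee-survey price level), utilities and DMFT flags of
# the ten tooth states; RepeatFilling is costed as Filling (minimum-cost
# assumption).  Death carries zeros by modelling decision.
_DEFAULT_TABLE: tuple[tuple[str, float, float, int], ...] = (
    ("NoDisease", 0.0, 1.00, 0),
    ("EnamelDecay", 0.0, 1.00, 0),
    ("DentineDecay", 0.0, 0.24, 1),
    ("Filling", 203.0, 0.77, 1),
    ("RepeatFilling", 203.0, 0.77, 1),
    ("RootCanal", 883.0, 0.77, 1),
    ("Crown", 1547.0, 0.77, 1),
    ("Extraction", 194.0, 0.56, 1),
    ("Bridge", 2710.0, 0.77, 1),
    ("Implant", 5316.0, 0.77, 1),
    ("Death", 0.0, 0.0, 0),
)


def default_states() -> list[HealthStateSpec]:
    """Base-case state specifications (all eleven states, canonical order)."""
    return [HealthStateSpec(n, c, u, d) for n, c, u, d in _DEFAULT_TABLE]


#: Discount rates used in the base case and its two sensitivity variants.
ALLOWED_DISCOUNT_RATES: tuple[float, ...] = (0.0, 0.035, 0.05)


@dataclass(frozen=True)
class ModelParams:
    """Scalar model parameters (base case by default).

    ``discount_timing`` selects the annual-step discounting convention used
    when accruing cycle amounts: ``"year_end"`` (default) discounts every
    amount in model year *y* by (1+r)^-(y+1), the ordinary-annuity
    convention of a spreadsheet NPV; ``"year_start"`` uses (1+r)^-y
    (annuity-due); ``"cycle_end"`` compounds continuously per cycle.
    """

    cycle_length: float = 0.5  # years
    start_age: float = 15.0
    end_age: float = 85.0
    n_molars: int = 8
    discount_rate: float = 0.05  # per annum
    prevented_fraction: float = 0.43
    prevented_fraction_low: float = 0.30
    prevented_fraction_high: float = 0.57
    intervention_cost_per_cycle: float = 37.70  # AUD per application cycle
    wtp_threshold: float = 28033.0  # AUD per QALY
    discount_timing: str = "year_end"
    half_cycle_correction: bool = False
    dmft_aggregation_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ConfigError("params.cycle_length", "must be positive")
        n = (self.end_age - self.start_age) / self.cycle_length
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ConfigError(
                "params.cycle_length",
                "horizon (end_age - start_age) must be an integer number of cycles",
            )
        if not (
            0.0
            <= self.prevented_fraction_low
            <= self.prevented_fraction
            <= self.prevented_fraction_high
            <= 1.0
        ):
            raise ConfigError(
                "params.prevented_fraction",
                "require 0 <= low <= pf <= high <= 1",
            )
        if self.discount_rate < 0:
            raise ConfigError("params.discount_rate", "must be >= 0")
        if self.discount_timing not in ("year_end", "year_start", "cycle_end"):
            raise ConfigError(
                "params.discount_timing",
                f"unknown timing {self.discount_timing!r}",
            )
        if self.intervention_cost_per_cycle < 0:
            raise ConfigError("params.intervention_cost_per_cycle", "must be >= 0")
        if self.n_molars < 1:
            raise ConfigError("params.n_molars", "must be >= 1")

    @property
    def n_cycles(self) -> int:
        """Number of 6-month transitions over the horizon (140 base case)."""
        return round((self.end_age - self.start_age) / self.cycle_length)

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_params() -> ModelParams:
    return ModelParams()


@dataclass(frozen=True)
class InitialDistribution:
    """Per-molar state distribution of the cohort at baseline (age 15).

    ``probabilities`` covers the ten tooth states in canonical order; the
    Death state starts with mass zero.
    """

    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probabilities) != len(TOOTH_STATE_NAMES):
            raise ConfigError(
                "initial_distribution",
                f"expected {len(TOOTH_STATE_NAMES)} entries, got "
                f"{len(self.probabilities)}",
            )
        if any(p < 0 for p in self.probabilities):
            raise ConfigError("initial_distribution", "negative probability")
        total = math.fsum(self.probabilities)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                "initial_distribution", f"probabilities sum to {total}, not 1"
            )

    def as_state_vector(self) -> np.ndarray:
        """Length-11 vector including Death mass 0."""
        return np.append(np.asarray(self.probabilities, dtype=float), 0.0)

    def __getitem__(self, name: str) -> float:
        return self.probabilities[state_index(name)]


# Baseline caries experience at age 15 per molar: 82.7% sound, 2.5% enamel
# decay, 0.3% dentine decay, 3.6% filled once, 10.9% missing; all other
# states empty.  Sums to 1 exactly.
_DEFAULT_INITIAL = (0.827, 0.025, 0.003, 0.036, 0.0, 0.0, 0.0, 0.109, 0.0, 0.0)


def default_initial_distribution() -> InitialDistribution:
    return InitialDistribution(_DEFAULT_INITIAL)


@dataclass
class ModelConfig:
    """A fully loaded model configuration.

    ``transitions`` and ``life_table`` are resolved objects
    (:class:`~cariescea.transitions.TransitionModel`,
    :class:`~cariescea.transitions.LifeTable`) when the config provided
    them, else ``None``.
    """

    states: list[HealthStateSpec]
    params: ModelParams
    initial_distribution: InitialDistribution
    transitions: object | None = None
    life_table: object | None = None
    generator_params: object | None = None

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    def cost_vector(self) -> np.ndarray:
        return np.array([s.unit_cost for s in self.states], dtype=float)

    def utility_vector(self) -> np.ndarray:
        return np.array([s.utility for s in self.states], dtype=float)

    def dmft_vector(self) -> np.ndarray:
        return np.array([float(s.dmft_flag) for s in self.states], dtype=float)


def default_config(resolve: bool = True) -> ModelConfig:
    """Base-case configuration; synthetic transitions/life table if ``resolve``."""
    cfg = ModelConfig(
        states=default_states(),
        params=default_params(),
        initial_distribution=default_initial_distribution(),
    )
    if resolve:
        from . import synthetic_data as sd

        gp = sd.default_generator_params()
        cfg.generator_params = gp
        cfg.transitions = sd.generate_transition_model(gp)
        cfg.life_table = sd.generate_life_table(
            gp.mortality_baseline, gp.mortality_doubling_years, seed=gp.seed
        )
    return cfg


_PARAM_FIELDS = (
    "cycle_length",
    "start_age",
    "end_age",
    "n_molars",
    "discount_rate",
    "prevented_fraction",
    "prevented_fraction_low",
    "prevented_fraction_high",
    "intervention_cost_per_cycle",
    "wtp_threshold",
    "discount_timing",
    "half_cycle_correction",
    "dmft_aggregation_factor",
)


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML model configuration.

    The document has sections ``states`` (list of name/unit_cost/utility/
    dmft_flag mappings), ``params`` (scalar overrides of the base case),
    ``initial_distribution`` (state-name -> probability mapping over the ten
    tooth states), and optionally ``transitions`` and ``life_table``, each
    either ``{csv: <path relative to the config file>}`` or a synthetic
    generator section (``{generator: {...}}`` / ``{gompertz: {...}}``).
    Every structural invariant is checked; violations raise
    :class:`ConfigError` naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError("path", f"config file {path} does not exist")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("document", "config must be a mapping")

    # states: default table overridden per name
    specs = {s.name: s for s in default_states()}
    for entry in doc.get("states", []) or []:
        name = entry.get("name")
        if name not in _STATE_INDEX:
            raise ConfigError("states.name", f"unknown state {name!r}")
        base = specs[name]
        specs[name] = HealthStateSpec(
            name=name,
            unit_cost=float(entry.get("unit_cost", base.unit_cost)),
            utility=float(entry.get("utility", base.utility)),
            dmft_flag=int(entry.get("dmft_flag", base.dmft_flag)),
        )
    states = [specs[n] for n in STATE_NAMES]

    raw_params = doc.get("params", {}) or {}
    unknown = set(raw_params) - set(_PARAM_FIELDS)
    if unknown:
        raise ConfigError("params", f"unknown parameter(s) {sorted(unknown)}")
    params = ModelParams(**{k: raw_params[k] for k in raw_params})
    if not any(
        math.isclose(params.discount_rate, r, abs_tol=1e-12)
        for r in ALLOWED_DISCOUNT_RATES
    ):
        raise ConfigError(
            "params.discount_rate",
            f"unknown discount rate {params.discount_rate}; "
            f"expected one of {ALLOWED_DISCOUNT_RATES}",
        )

    init_section = doc.get("initial_distribution")
    if init_section is None:
        init = default_initial_distribution()
    else:
        probs = [0.0] * len(TOOTH_STATE_NAMES)
        for name, p in init_section.items():
            idx = state_index(name)
            if idx == DEATH_STATE:
                raise ConfigError(
                    "initial_distribution", "Death may not carry initial mass"
                )
            probs[idx] = float(p)
        init = InitialDistribution(tuple(probs))

    cfg = ModelConfig(states=states, params=params, initial_distribution=init)

    from . import synthetic_data as sd
    from . import transitions as tr

    tsec = doc.get("transitions")
    if tsec:
        if "csv" in tsec:
            cfg.transitions = tr.read_transition_csv(path.parent / tsec["csv"])
        elif "generator" in tsec:
            gp = sd.GeneratorParams.from_dict(tsec["generator"])
            cfg.generator_params = gp
            cfg.transitions = sd.generate_transition_model(gp)
        else:
            raise ConfigError("transitions", "need a 'csv' or 'generator' entry")

    lsec = doc.get("life_table")
    if lsec:
        if "csv" in lsec:
            cfg.life_table = tr.read_life_table_csv(path.parent / lsec["csv"])
        elif "gompertz" in lsec:
            g = lsec["gompertz"]
            cfg.life_table = sd.generate_life_table(
                float(g["baseline"]),
                float(g.get("doubling_years", 10.0)),
                start_age=int(cfg.params.start_age),
                end_age=int(cfg.params.end_age),
            )
        else:
            raise ConfigError("life_table", "need a 'csv' or 'gompertz' entry")
    return cfg


def write_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write states, params and initial distribution back to YAML.

    Transition matrices and life tables are referenced by CSV next to the
    config file when present on ``cfg``.
    """
    path = Path(path)
    doc: dict = {
        "states": [
            {
                "name": s.name,
                "unit_cost": s.unit_cost,
                "utility": s.utility,
                "dmft_flag": s.dmft_flag,
            }
            for s in cfg.states
        ],
        "params": {k: getattr(cfg.params, k) for k in _PARAM_FIELDS},
        "initial_distribution": {
            name: p
            for name, p in zip(TOOTH_STATE_NAMES, cfg.initial_distribution.probabilities)
        },
    }
    if cfg.transitions is not None:
        from . import transitions as tr

        csv_path = path.with_suffix(".transitions.csv")
        tr.write_transition_csv(cfg.transitions, csv_path)
        doc["transitions"] = {"csv": csv_path.name}
    if cfg.life_table is not None:
        from . import transitions as tr

        csv_path = path.with_suffix(".life_table.csv")
        tr.write_life_table_csv(cfg.life_table, csv_path)
        doc["life_table"] = {"csv": csv_path.name}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
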