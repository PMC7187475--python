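"""Age-indexed transition matrices: validation, mortality, prevented fraction.

A :class:`TransitionModel` maps integer age bands to 11x11 row-stochastic
matrices over the canonical state order (ten tooth states + Death).  Ages
beyond the last supplied band reuse the last band's matrix (the 75+
extrapolation rule).  Background mortality from a :class:`LifeTable` is
folded in per cycle, uniformly across tooth states.  The intervention arm
is produced by :func:`apply_prevented_fraction`, which scales selected
caries transitions down by the prevented fraction and returns the removed
mass to the source state's self-transition (the tooth stays in its current
state longer).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model_core import (
    DEATH_STATE,
    N_STATES,
    STATE_NAMES,
    ModelParams,
    state_index,
)

__all__ = [
    "TransitionModel",
    "LifeTable",
    "TransitionValidationError",
    "validate_transition_model",
    "augment_with_mortality",
    "apply_prevented_fraction",
    "matrix_for_cycle",
    "read_transition_csv",
    "write_transition_csv",
    "read_life_table_csv",
    "write_life_table_csv",
]

_ROW_TOL = 1e-9


class TransitionValidationError(ValueError):
    """A transition model or life table violates a structural invariant."""


@dataclass
class TransitionModel:
    """Age-indexed row-stochastic matrices over the 11 canonical states."""

    matrices: dict[int, np.ndarray]

    @property
    def ages(self) -> list[int]:
        return sorted(self.matrices)

    @property
    def min_age(self) -> int:
        return min(self.matrices)

    @property
    def max_age(self) -> int:
        return max(self.matrices)

    def matrix_at_age(self, age: int) -> np.ndarray:
        """Matrix for an integer age, clamped into the covered band range."""
        age = int(min(max(age, self.min_age), self.max_age))
        return self.matrices[age]

    def copy(self) -> "TransitionModel":
        return TransitionModel({a: m.copy() for a, m in self.matrices.items()})


@dataclass
class LifeTable:
    """Annual probability of death q(age) for integer ages."""

    q: dict[int, float]

    def __post_init__(self) -> None:
        for age, qa in self.q.items():
            if not 0.0 <= qa <= 1.0:
                raise TransitionValidationError(
                    f"life table q({age}) = {qa} outside [0, 1]"
                )

    def q_at(self, age: int) -> float:
        age = int(age)
        try:
            return self.q[age]
        except KeyError:
            raise TransitionValidationError(
                f"life table has no entry for age {age}"
            ) from None


def validate_transition_model(
    model: TransitionModel,
    required_ages: Iterable[int] | None = None,
    forbid_nodisease_reentry: bool = True,
) -> TransitionModel:
    """Check structural invariants; return the model unchanged if they hold.

    Invariants: every row sums to 1 within 1e-9 with entries in [0, 1]; the
    Death row is absorbing; no state re-enters NoDisease (caries history is
    irreversible).  ``required_ages`` (default: min..max of the supplied
    bands, at least 15..75) must all be present.
    """
    if not model.matrices:
        raise TransitionValidationError("transition model has no age bands")
    if required_ages is None:
        required_ages = range(model.min_age, model.max_age + 1)
    missing = [a for a in required_ages if a not in model.matrices]
    if missing:
        raise TransitionValidationError(f"missing age band(s): {missing}")
    for age in model.ages:
        m = model.matrices[age]
        if m.shape != (N_STATES, N_STATES):
            raise TransitionValidationError(
                f"age {age}: matrix shape {m.shape}, expected "
                f"({N_STATES}, {N_STATES})"
            )
        if np.any(m < -1e-15) or np.any(m > 1 + 1e-12):
            bad = np.argwhere((m < -1e-15) | (m > 1 + 1e-12))[0]
            raise TransitionValidationError(
                f"age {age}: entry {STATE_NAMES[bad[0]]}->{STATE_NAMES[bad[1]]} "
                f"= {m[bad[0], bad[1]]} outside [0, 1]"
            )
        sums = m.sum(axis=1)
        bad_rows = np.where(np.abs(sums - 1.0) > _ROW_TOL)[0]
        if bad_rows.size:
            r = bad_rows[0]
            raise TransitionValidationError(
                f"age {age}: row {STATE_NAMES[r]} sums to {sums[r]:.12g}, not 1"
            )
        death_row = np.zeros(N_STATES)
        death_row[DEATH_STATE] = 1.0
        if not np.allclose(m[DEATH_STATE], death_row, atol=_ROW_TOL):
            raise TransitionValidationError(
                f"age {age}: Death row is not absorbing"
            )
        if forbid_nodisease_reentry:
            col0 = m[1:, 0]
            if np.any(col0 > 1e-15):
                src = int(np.argmax(col0 > 1e-15)) + 1
                raise TransitionValidationError(
                    f"age {age}: forbidden re-entry into NoDisease from "
                    f"{STATE_NAMES[src]}"
                )
    return model


def augment_with_mortality(
    model: TransitionModel,
    life: LifeTable,
    cycle_length: float,
    end_age: int | None = None,
) -> TransitionModel:
    """Fold per-cycle background mortality into the tooth-state matrices.

    The per-cycle death probability at age *a* is p = 1 - (1 - q_a)^cycle,
    applied uniformly: every tooth-state row is scaled by (1 - p) and p is
    added to its Death column.  When ``end_age`` exceeds the model's last
    band, extra bands are created that reuse the last band's tooth dynamics
    but the actual age's mortality, so the 75+ extrapolation applies to
    caries progression while mortality keeps rising with age.
    """
    last = int(end_age) - 1 if end_age is not None else model.max_age
    out: dict[int, np.ndarray] = {}
    for age in range(model.min_age, last + 1):
        q = life.q_at(age)
        p = 1.0 - (1.0 - q) ** cycle_length
        m = model.matrix_at_age(age).copy()
        tooth = slice(0, DEATH_STATE)
        m[tooth, :] *= 1.0 - p
        m[tooth, DEATH_STATE] += p
        m[DEATH_STATE, :] = 0.0
        m[DEATH_STATE, DEATH_STATE] = 1.0
        out[age] = m
    return TransitionModel(out)


def apply_prevented_fraction(
    model: TransitionModel,
    pf: float,
    affected: Iterable[tuple[str, str]],
) -> TransitionModel:
    """Scale each affected transition by (1 - pf); keep rows stochastic.

    For every affected ordered pair (source, target) the transition
    probability becomes p * (1 - pf) in every age band, and the removed
    mass p * pf is added to the source state's self-transition: the varnish
    holds the tooth in its current state rather than rerouting it.  Row
    sums are preserved exactly by construction.
    """
    if not 0.0 <= pf <= 1.0:
        raise ValueError(f"prevented fraction {pf} outside [0, 1]")
    pairs = []
    for src, dst in affected:
        i, j = state_index(src), state_index(dst)
        if i == j:
            raise ValueError(f"affected pair {src}->{dst} is a self-transition")
        pairs.append((i, j))
    out = model.copy()
    for m in out.matrices.values():
        for i, j in pairs:
            removed = m[i, j] - m[i, j] * (1.0 - pf)
            m[i, j] -= removed
            m[i, i] += removed
    return out


def matrix_for_cycle(
    model: TransitionModel, cycle_index: int, params: ModelParams
) -> np.ndarray:
    """Matrix governing transition ``cycle_index`` -> ``cycle_index + 1``.

    The age band is floor(start_age + k * cycle_length), clamped into the
    model's covered range (so ages past the last band reuse it).
    """
    if not 0 <= cycle_index < params.n_cycles:
        raise IndexError(
            f"cycle index {cycle_index} outside [0, {params.n_cycles})"
        )
    age = int(np.floor(params.start_age + cycle_index * params.cycle_length))
    return model.matrix_at_age(age)


# ---------------------------------------------------------------------------
# CSV interchange (long format: age, from_state, to_state, probability)

def read_transition_csv(path: str | Path) -> TransitionModel:
    df = pd.read_csv(path)
    required = {"age", "from_state", "to_state", "probability"}
    if not required.issubset(df.columns):
        raise TransitionValidationError(
            f"transition CSV needs columns {sorted(required)}"
        )
    for col in ("from_state", "to_state"):
        unknown = set(df[col]) - set(STATE_NAMES)
        if unknown:
            raise TransitionValidationError(
                f"unknown state name(s) in {col}: {sorted(unknown)}"
            )
    matrices: dict[int, np.ndarray] = {}
    for age, grp in df.groupby("age"):
        m = np.zeros((N_STATES, N_STATES))
        idx_from = grp["from_state"].map(state_index).to_numpy()
        idx_to = grp["to_state"].map(state_index).to_numpy()
        m[idx_from, idx_to] = grp["probability"].to_numpy(dtype=float)
        matrices[int(age)] = m
    return validate_transition_model(TransitionModel(matrices))


def write_transition_csv(model: TransitionModel, path: str | Path) -> None:
    rows = []
    for age in model.ages:
        m = model.matrices[age]
        nz = np.argwhere(m != 0.0)
        for i, j in nz:
            rows.append((age, STATE_NAMES[i], STATE_NAMES[j], m[i, j]))
    pd.DataFrame(
        rows, columns=["age", "from_state", "to_state", "probability"]
    ).to_csv(path, index=False)


def read_life_table_csv(path: str | Path) -> LifeTable:
    df = pd.read_csv(path)
    if not {"age", "q"}.issubset(df.columns):
        raise TransitionValidationError("life table CSV needs columns age,q")
    return LifeTable({int(a): float(q) for a, q in zip(df["age"], df["q"])})


def write_life_table_csv(life: LifeTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(life.q.items()), columns=["age", "q"]
    ).to_csv(path, index=False)
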