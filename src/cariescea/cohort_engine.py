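"""Markov cohort recursion for one molar under one arm.

``run_cohort`` propagates the expected state distribution of a single molar
through the cycle-indexed transition matrices and records, per cycle, both
the occupancy vector and the incident probability mass *entering* each
state (used for event-based costing: a filling is paid for when the tooth
enters Filling, not while it stays there).

``enumerate_paths_oracle`` recomputes the same trace by explicit summation
over all state paths; it is deliberately brute force and only accepts tiny
instances, serving as an independent cross-check of the matrix recursion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import (
    DEATH_STATE,
    STATE_NAMES,
    InitialDistribution,
    ModelParams,
)
from .transitions import TransitionModel, matrix_for_cycle

__all__ = ["CohortTrace", "run_cohort", "enumerate_paths_oracle"]


@dataclass
class CohortTrace:
    """Per-cycle occupancy and incident-entry mass for one molar/arm.

    ``occupancy[k]`` is the state distribution after k transitions
    (cycle 0 = baseline); ``entries[k]`` is the probability mass that moved
    into each state on transition k (``entries[0]`` is all zero — baseline
    prevalence is not an incident event).
    """

    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    entries: np.ndarray  # (n_cycles + 1, n_states)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def n_states(self) -> int:
        return self.occupancy.shape[1]

    def survival(self) -> np.ndarray:
        """Fraction of the cohort alive at each cycle (1 - Death mass)."""
        return 1.0 - self.occupancy[:, DEATH_STATE]

    def to_dataframe(self, params: ModelParams | None = None) -> pd.DataFrame:
        """Long-format trace: cycle, age, state, occupancy, incident_entry."""
        n_c, n_s = self.occupancy.shape
        cycles = np.repeat(np.arange(n_c), n_s)
        states = np.tile(
            np.array(STATE_NAMES[:n_s] if n_s <= len(STATE_NAMES) else
                     [str(i) for i in range(n_s)]),
            n_c,
        )
        df = pd.DataFrame(
            {
                "cycle": cycles,
                "state": states,
                "occupancy": self.occupancy.ravel(),
                "incident_entry": self.entries.ravel(),
            }
        )
        if params is not None:
            df.insert(1, "age", params.start_age + df["cycle"] * params.cycle_length)
        return df

    def to_csv(self, path: str | Path, params: ModelParams | None = None) -> None:
        self.to_dataframe(params).to_csv(path, index=False)


def _resolve_matrices(
    model: TransitionModel | np.ndarray | Sequence[np.ndarray],
    n_cycles: int,
    params: ModelParams | None,
) -> list[np.ndarray]:
    if isinstance(model, TransitionModel):
        if params is None:
            raise ValueError("params required with a TransitionModel")
        return [matrix_for_cycle(model, k, params) for k in range(n_cycles)]
    if isinstance(model, np.ndarray):
        return [model] * n_cycles
    mats = list(model)
    if len(mats) == 1:
        return mats * n_cycles
    if len(mats) != n_cycles:
        raise ValueError(
            f"got {len(mats)} matrices for {n_cycles} cycles"
        )
    return mats


def _init_vector(
    init: InitialDistribution | np.ndarray | Sequence[float], n_states: int
) -> np.ndarray:
    if isinstance(init, InitialDistribution):
        v = init.as_state_vector()
    else:
        v = np.asarray(init, dtype=float)
    if v.shape != (n_states,):
        raise ValueError(
            f"initial distribution has {v.shape} entries, matrices are "
            f"{n_states}-state"
        )
    return v


def run_cohort(
    model: TransitionModel | np.ndarray | Sequence[np.ndarray],
    init: InitialDistribution | np.ndarray | Sequence[float],
    params: ModelParams | None = None,
    *,
    n_cycles: int | None = None,
) -> CohortTrace:
    """Propagate the cohort distribution over ``n_cycles`` transitions.

    occupancy(k+1) = occupancy(k) @ P_k and
    entries(k+1)[t] = sum_{s != t} occupancy(k)[s] P_k[s, t].

    ``model`` may be a :class:`TransitionModel` (with ``params`` supplying
    ages), a single matrix reused every cycle, or one matrix per cycle.
    """
    if n_cycles is None:
        if params is None:
            raise ValueError("need params or n_cycles")
        n_cycles = params.n_cycles
    mats = _resolve_matrices(model, n_cycles, params)
    n_states = mats[0].shape[0]
    v = _init_vector(init, n_states)

    occ = np.empty((n_cycles + 1, n_states))
    ent = np.zeros((n_cycles + 1, n_states))
    occ[0] = v
    for k in range(n_cycles):
        m = mats[k]
        if m.shape != (n_states, n_states):
            raise ValueError(f"cycle {k}: matrix shape {m.shape} mismatch")
        occ[k + 1] = occ[k] @ m
        off_diag = m - np.diag(np.diag(m))
        ent[k + 1] = occ[k] @ off_diag
    return CohortTrace(occupancy=occ, entries=ent)


_MAX_ORACLE_PATHS = 500_000


def enumerate_paths_oracle(
    model: TransitionModel | np.ndarray | Sequence[np.ndarray],
    init: InitialDistribution | np.ndarray | Sequence[float],
    n_cycles: int,
    params: ModelParams | None = None,
) -> CohortTrace:
    """Brute-force trace by summing over every explicit state path.

    Only small instances are accepted (the path count n_states^(n+1) must
    stay under half a million); intended purely as an independent oracle
    for :func:`run_cohort`.
    """
    mats = _resolve_matrices(model, n_cycles, params)
    n_states = mats[0].shape[0]
    if n_states ** (n_cycles + 1) > _MAX_ORACLE_PATHS:
        raise ValueError(
            f"instance too large for path enumeration: "
            f"{n_states}^{n_cycles + 1} paths"
        )
    v = _init_vector(init, n_states)

    occ = np.zeros((n_cycles + 1, n_states))
    ent = np.zeros((n_cycles + 1, n_states))
    occ[0] = v
    for k in range(1, n_cycles + 1):
        for path in product(range(n_states), repeat=k + 1):
            p = v[path[0]]
            for step in range(k):
                p *= mats[step][path[step], path[step + 1]]
                if p == 0.0:
                    break
            if p == 0.0:
                continue
            occ[k, path[-1]] += p
            if path[-2] != path[-1]:
                ent[k, path[-1]] += p
    return CohortTrace(occupancy=occ, entries=ent)
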