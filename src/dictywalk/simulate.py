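"""Monte-Carlo trajectory ensembles.

Each simulated cell carries a pair-state chain; every sampled direction
moves the centroid by a fixed step (6 um by default, one step per 20 s),
along the new pseudopod direction.  Cells are independent: cell ``k`` of
a run with seed ``s`` draws from ``numpy``'s ``default_rng([s, k])``
substream, so ensembles are bit-reproducible and independent of
execution order, and any subset of cells can be regenerated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .chemotaxis import CouplingParams, build_perturbed_matrix
from .directions import UNIT_VECTORS
from .markov import (
    DENOVO,
    MOVE_LABELS,
    N_STATES,
    SPLIT_CCW,
    SPLIT_CW,
    STATE_CURR,
    STATE_DELTA,
    STATES,
    ModelParams,
    PairState,
    TransitionMatrix,
    build_transition_matrix,
)
from .stationary import closed_form_stationary

MOVE_CODES = {SPLIT_CCW: 0, SPLIT_CW: 1, DENOVO: 2}

#: move code of the transition *into* each state, by state index
_STATE_MOVE_CODE = np.where(STATE_DELTA == 1, 0, np.where(STATE_DELTA == 5, 1, 2))


@dataclass(frozen=True)
class SimulationConfig:
    """Ensemble size, time discretization and model parameters.

    ``dt`` is in seconds (default 20 s per step) and ``step_length`` in
    micrometres (default 6 um); times reported on trajectories are in
    minutes.  ``init_mode='stationary'`` draws the initial direction
    pair from the homogeneous invariant distribution so the motility
    statistics carry no initialization transient; ``'uniform'`` draws
    uniformly over the 30 pair states.
    """

    n_cells: int = 1
    n_steps: int = 45
    dt: float = 20.0
    step_length: float = 6.0
    params: ModelParams = field(default_factory=ModelParams)
    coupling: CouplingParams | None = None
    seed: int = 0
    init_mode: Literal["stationary", "uniform"] = "stationary"

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_steps < 1:
            raise ValueError("n_cells and n_steps must be at least 1")
        if self.dt <= 0 or self.step_length <= 0:
            raise ValueError("dt and step_length must be positive")
        if self.init_mode not in ("stationary", "uniform"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Positions, directions and move types of ``n_cells`` random walks.

    ``positions`` has shape ``(n_cells, n_steps + 1, 2)`` in um with
    every trajectory starting at the origin; ``directions`` (1..6) and
    ``move_types`` (integer codes per :data:`MOVE_CODES`) have shape
    ``(n_cells, n_steps)``, one entry per executed step.
    """

    config: SimulationConfig
    positions: np.ndarray
    directions: np.ndarray
    move_types: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_steps(self) -> int:
        return self.directions.shape[1]

    @property
    def times_min(self) -> np.ndarray:
        """Time of each stored position, minutes (index 0 is t = 0)."""
        return np.arange(self.n_steps + 1) * self.config.dt / 60.0

    def move_labels(self) -> np.ndarray:
        return np.array(MOVE_LABELS, dtype=object)[self.move_types]


def initial_pair(
    rng: np.random.Generator,
    params: ModelParams,
    init_mode: str = "stationary",
) -> PairState:
    """Draw one starting pair state."""
    idx = _draw_initial_indices(rng, params, init_mode, 1)[0]
    return STATES[idx]


def _initial_weights(params: ModelParams, init_mode: str) -> np.ndarray:
    if init_mode == "stationary":
        return closed_form_stationary(params).vector
    if init_mode == "uniform":
        return np.full(N_STATES, 1.0 / N_STATES)
    raise ValueError(f"unknown init_mode {init_mode!r}")


def _draw_initial_indices(rng, params, init_mode, size) -> np.ndarray:
    cum = np.cumsum(_initial_weights(params, init_mode))
    u = rng.random(size)
    return np.searchsorted(cum, u, side="right")


def step(
    pair: PairState, P: TransitionMatrix, rng: np.random.Generator
) -> tuple[PairState, str]:
    """One chain transition; returns the new pair and its move label."""
    row = P.entries[STATES.index(pair)]
    s = row.sum()
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"transition row is not normalized (sum {s:g})")
    j = int(np.searchsorted(np.cumsum(row), rng.random(), side="right"))
    j = min(j, N_STATES - 1)  # guard the measure-zero u == 1 edge
    nxt = STATES[j]
    return nxt, MOVE_LABELS[_STATE_MOVE_CODE[j]]


def simulate(config: SimulationConfig) -> TrajectoryEnsemble:
    """Run the ensemble.

    The chain of every cell is advanced with a vectorized categorical
    sampler over the 30 states; with a gradient coupling configured the
    biased matrix is used (and an over-strong coupling is refused before
    any work is done).
    """
    P0 = build_transition_matrix(config.params)
    if config.coupling is not None and config.coupling.epsilon > 0:
        P = build_perturbed_matrix(P0, config.coupling)
    else:
        P = P0

    n, T = config.n_cells, config.n_steps
    # Per-cell substreams: cell k consumes 1 + T uniforms from rng([seed, k]).
    u_init = np.empty(n)
    u_steps = np.empty((n, T))
    for k in range(n):
        rng = np.random.default_rng([config.seed, k])
        u_init[k] = rng.random()
        u_steps[k] = rng.random(T)

    cum_init = np.cumsum(_initial_weights(config.params, config.init_mode))
    state = np.searchsorted(cum_init, u_init, side="right")
    np.clip(state, 0, N_STATES - 1, out=state)

    cum_rows = np.cumsum(P.entries, axis=1)
    cum_rows[:, -1] = 1.0  # close roundoff at the top of each row

    directions = np.empty((n, T), dtype=np.int64)
    move_types = np.empty((n, T), dtype=np.int64)
    for t in range(T):
        # next state index = first column whose cumulative weight covers u
        state = (cum_rows[state] < u_steps[:, t, None]).sum(axis=1)
        directions[:, t] = STATE_CURR[state]
        move_types[:, t] = _STATE_MOVE_CODE[state]

    steps_xy = config.step_length * UNIT_VECTORS[directions - 1]
    positions = np.zeros((n, T + 1, 2))
    np.cumsum(steps_xy, axis=1, out=positions[:, 1:])
    return TrajectoryEnsemble(config, positions, directions, move_types)
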