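"""Invariant distribution of the pair-state chain.

The stationary (invariant) distribution ``omega0`` is the left unit
eigenvector of the transition matrix, ``omega0 (I - P0) = 0``.  For the
homogeneous chain it has a simple closed form when rearranged as a
6 x 6 array over ``(prev, curr)``: adjacent-direction pairs (a single
``pi/3`` turn apart) carry probability ``(1 - p)/12`` each and all other
off-diagonal pairs carry ``p/18``, independently of the split-handedness
weights ``alpha`` and ``beta`` — the chain's one-step memory is
invisible in the long run.  The marginal over directions is uniform,
1/6 each.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .directions import N_DIRECTIONS
from .markov import (
    N_STATES,
    STATES,
    ModelParams,
    PairState,
    TransitionMatrix,
)

#: Numerically, eigenvalue-1 multiplicity > 1 (a reducible chain) is flagged
#: when the second-largest eigenvalue modulus exceeds 1 - _GAP_TOL.
_GAP_TOL = 1e-8

_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class StationaryDistribution:
    """Probability vector over the 30 pair states, canonical order."""

    vector: np.ndarray
    states: tuple[PairState, ...] = field(default=STATES)
    params_used: ModelParams | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if v.shape != (N_STATES,):
            raise ValueError(f"expected a 30-vector, got shape {v.shape}")
        object.__setattr__(self, "vector", v)

    @property
    def rearranged(self) -> np.ndarray:
        """6 x 6 array indexed ``[prev - 1, curr - 1]`` with zero diagonal."""
        out = np.zeros((N_DIRECTIONS, N_DIRECTIONS))
        for s, w in zip(self.states, self.vector):
            out[s.prev - 1, s.curr - 1] = w
        return out

    def probability(self, state: PairState) -> float:
        return float(self.vector[self.states.index(state)])

    # -- serialization -------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """6 x 6 rearranged form with direction labels."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            labels = [str(n) for n in range(1, N_DIRECTIONS + 1)]
            w.writerow(["prev\\curr"] + labels)
            for lab, row in zip(labels, self.rearranged):
                w.writerow([lab] + [repr(float(x)) for x in row])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "state_order": [s.label for s in self.states],
                    "vector": self.vector.tolist(),
                }
            )
        )


def solve_stationary(P: TransitionMatrix) -> StationaryDistribution:
    """Left unit eigenvector of ``P``, normalized to a probability vector.

    Raises
    ------
    ValueError
        If the unit eigenvalue is (numerically) degenerate, which
        signals a reducible chain — e.g. some ``p = 0`` edge cases —
        rather than silently picking one invariant measure among many.
    """
    vals, vecs = scipy.linalg.eig(P.entries.T)
    closest = int(np.argmin(np.abs(vals - 1.0)))
    if abs(vals[closest] - 1.0) > 1e-8:
        raise ValueError("matrix has no unit eigenvalue; is it row-stochastic?")
    if np.sum(np.abs(vals) > 1.0 - _GAP_TOL) > 1:
        raise ValueError(
            "unit eigenvalue is degenerate: the chain is reducible and has "
            "no unique stationary distribution"
        )
    v = np.real(vecs[:, closest])
    v = v * np.sign(v.sum())
    if np.min(v / v.sum()) < -1e-12:
        raise ValueError("stationary eigenvector has a significant negative entry")
    v = np.clip(v, 0.0, None)
    v = v / v.sum()
    residual = np.max(np.abs(v @ P.entries - v))
    if residual > _RESIDUAL_TOL:
        raise ValueError(f"stationary residual too large: {residual:g}")
    return StationaryDistribution(v)


def closed_form_stationary(params: ModelParams) -> StationaryDistribution:
    """Homogeneous-medium invariant distribution, built analytically.

    Adjacent pairs (turn of one lattice step either way) get
    ``(1 - p)/12``; the three wide-turn pairs get ``p/18`` each.  Total
    mass is ``6 * (2 (1-p)/12 + 3 p/18) = 1`` identically.
    """
    v = np.empty(N_STATES)
    for i, s in enumerate(STATES):
        if s.delta in (1, 5):
            v[i] = (1.0 - params.p) / 12.0
        else:
            v[i] = params.p / 18.0
    return StationaryDistribution(v, params_used=params)


def marginal_direction_probs(omega: StationaryDistribution) -> np.ndarray:
    """Probability of each of the six current directions under ``omega``.

    Column sums of the rearranged 6 x 6 array (summing out the previous
    direction).  In a homogeneous medium each component equals 1/6; a
    gradient-biased chain tilts mass toward the directions aligned with
    the gradient.
    """
    return omega.rearranged.sum(axis=0)
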