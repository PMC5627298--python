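"""Pair-state space and homogeneous transition matrix.

The pseudopod growth direction is a second-order Markov process: the
next direction depends on the current *and* the previous one.  Tracking
the ordered pair ``(prev, curr)`` of consecutive directions restores the
Markov property.  Repeating a direction is forbidden, so there are
``6 * 5 = 30`` pair states, and the chain is described by a 30 x 30
row-stochastic matrix ``P0``.

Generative rule (homogeneous medium)
------------------------------------
From pair ``(m, n)`` the next direction ``n'`` (never equal to ``n``) is
drawn as:

* with probability ``p`` a *de novo* pseudopod appears at the cell rear:
  ``n'`` is uniform over the three directions at least ``2*pi/3`` away
  from ``n`` (probability ``p/3`` each), regardless of how ``(m, n)``
  itself arose;
* otherwise (probability ``1 - p``) the current pseudopod *splits* to
  ``n + 1`` or ``n - 1``:

  - if the move ``m -> n`` was itself a split of handedness ``h``,
    the split continues with the same handedness with weight ``alpha``
    and alternates with weight ``beta`` (``alpha + beta = 1``);
  - if ``m -> n`` was de novo, the two split targets are equally likely.

With the default ``beta/alpha = 3`` the model reproduces the observation
that alternating left/right split sequences are about three times more
common than same-handed ones.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .directions import N_DIRECTIONS

N_STATES = 30

SPLIT_CCW = "split_ccw"
SPLIT_CW = "split_cw"
DENOVO = "denovo"

#: Move-type labels in the fixed integer encoding used by the simulator.
MOVE_LABELS = (SPLIT_CCW, SPLIT_CW, DENOVO)

ROW_SUM_TOL = 1e-12


@dataclass(frozen=True, order=True)
class PairState:
    """Ordered pair of consecutive pseudopod directions ``(prev, curr)``."""

    prev: int
    curr: int

    def __post_init__(self) -> None:
        for n in (self.prev, self.curr):
            if not (isinstance(n, (int, np.integer)) and 1 <= n <= N_DIRECTIONS):
                raise ValueError(f"direction index must be in 1..6, got {n!r}")
        if self.prev == self.curr:
            raise ValueError(
                f"repeated direction {self.curr} is forbidden: a pseudopod "
                "never grows twice in a row along the same direction"
            )

    @property
    def delta(self) -> int:
        """Turn ``(curr - prev) mod 6``; always in 1..5."""
        return (self.curr - self.prev) % N_DIRECTIONS

    @property
    def label(self) -> str:
        return f"{self.prev}-{self.curr}"


@dataclass(frozen=True)
class ModelParams:
    """Homogeneous-medium parameters.

    Parameters
    ----------
    p:
        Probability of a de novo pseudopod per step.  Default 1/7: a
        splitting pseudopod is observed about seven times more often
        than a de novo one.
    alpha:
        Weight of a same-handed (consecutive) split.
    beta:
        Weight of an alternating split; ``alpha + beta = 1``.  The
        default pair (0.25, 0.75) sets alternating/consecutive = 3.
    """

    p: float = 1.0 / 7.0
    alpha: float = 0.25
    beta: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError(
                f"alpha + beta must equal 1, got {self.alpha + self.beta}"
            )


def enumerate_states() -> tuple[PairState, ...]:
    """All 30 pair states in lexicographic ``(prev, curr)`` order.

    The ordering is the canonical state order used everywhere in the
    package (matrix rows/columns, serialized vectors); it is stable
    across calls and releases.
    """
    return tuple(
        PairState(prev, curr)
        for prev in range(1, N_DIRECTIONS + 1)
        for curr in range(1, N_DIRECTIONS + 1)
        if prev != curr
    )


STATES: tuple[PairState, ...] = enumerate_states()
STATE_INDEX: dict[PairState, int] = {s: i for i, s in enumerate(STATES)}

# Flat lookup arrays over the canonical order, used by the vectorized simulator.
STATE_PREV = np.array([s.prev for s in STATES])
STATE_CURR = np.array([s.curr for s in STATES])
STATE_DELTA = np.array([s.delta for s in STATES])


def classify_move(pair: PairState) -> str:
    """Label the move ``prev -> curr`` as a split (by handedness) or de novo.

    A turn of ``+pi/3`` (index +1, counterclockwise) is ``split_ccw``, a
    turn of ``-pi/3`` is ``split_cw``; turns of ``2*pi/3`` or more are
    de novo extensions at the cell rear.
    """
    d = pair.delta
    if d == 1:
        return SPLIT_CCW
    if d == 5:
        return SPLIT_CW
    return DENOVO


def transition_prob(frm: PairState, to: PairState, params: ModelParams) -> float:
    """Single entry ``P0[(frm) -> (to)]`` of the homogeneous chain."""
    if to.prev != frm.curr:
        return 0.0
    d_next = to.delta  # turn of the prospective move, relative to frm.curr
    if d_next in (2, 3, 4):
        return params.p / 3.0
    # split move
    if frm.delta in (2, 3, 4):  # previous move was de novo: unbiased split
        return (1.0 - params.p) / 2.0
    same_handed = d_next == frm.delta
    w = params.alpha if same_handed else params.beta
    return (1.0 - params.p) * w


@dataclass(frozen=True)
class TransitionMatrix:
    """30 x 30 row-stochastic matrix over the canonical pair-state order."""

    entries: np.ndarray
    states: tuple[PairState, ...] = field(default=STATES)

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.shape != (N_STATES, N_STATES):
            raise ValueError(f"expected a 30x30 matrix, got shape {m.shape}")
        if np.any(m < -ROW_SUM_TOL) or np.any(m > 1.0 + ROW_SUM_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rs = m.sum(axis=1)
        if np.max(np.abs(rs - 1.0)) > 1e-9:
            raise ValueError("every row must sum to 1")
        object.__setattr__(self, "entries", m)

    def __getitem__(self, key) -> float:
        frm, to = key
        return float(self.entries[STATE_INDEX[frm], STATE_INDEX[to]])

    def row_sums(self) -> np.ndarray:
        return self.entries.sum(axis=1)

    # -- serialization -------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV with 'prev-curr' labels on the header row/column."""
        labels = [s.label for s in self.states]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["state"] + labels)
            for lab, row in zip(labels, self.entries):
                w.writerow([lab] + [repr(float(x)) for x in row])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "state_order": [s.label for s in self.states],
            "entries": self.entries.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransitionMatrix":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        header = rows[0][1:]
        expected = [s.label for s in STATES]
        if header != expected:
            raise ValueError("state order in CSV does not match the canonical order")
        m = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
        return cls(m)

    @classmethod
    def from_json(cls, path: str | Path) -> "TransitionMatrix":
        payload = json.loads(Path(path).read_text())
        if payload["state_order"] != [s.label for s in STATES]:
            raise ValueError("state order in JSON does not match the canonical order")
        return cls(np.array(payload["entries"], dtype=float))


def build_transition_matrix(params: ModelParams) -> TransitionMatrix:
    """Assemble the homogeneous 30 x 30 transition matrix ``P0``.

    For generic parameters (``0 < p < 1``, ``alpha, beta > 0``) every
    row has exactly five nonzero entries: two splits and three de novo
    targets.
    """
    m = np.zeros((N_STATES, N_STATES))
    for i, frm in enumerate(STATES):
        for j, to in enumerate(STATES):
            m[i, j] = transition_prob(frm, to, params)
    return TransitionMatrix(m)


def classify_moves(pairs: Iterable[PairState]) -> list[str]:
    return [classify_move(p) for p in pairs]
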