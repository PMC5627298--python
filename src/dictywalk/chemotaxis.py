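"""Gradient-biased transition matrix and weak-coupling perturbation theory.

A chemoattractant (cAMP) gradient biases the direction of pseudopod
extension without bending individual pseudopodia.  The bias is additive:

    P = P0 + epsilon * Delta,

where ``Delta[(m, n) -> (n, n')] = g . n_hat(n')`` is the inner product
between the prospective direction and the (unit) gradient direction
``g``, and ``epsilon = gamma * L * |grad C| / C`` is a dimensionless
coupling coefficient combining the cell size ``L``, the local
concentration ``C`` and its gradient.  The back-step — extending
opposite to the current direction, at the cell posterior — is excluded
from the bias and keeps its unbiased probability.  The four biased
targets then come in opposite-direction pairs, so each row of ``Delta``
sums to zero exactly and ``P`` stays row-stochastic by construction.

Mirror symmetry about the gradient axis (parity) is preserved; the
homogeneous index-translation symmetry is broken.

The weak-coupling regime is the range of ``epsilon`` for which every
entry of ``P`` remains a probability; :func:`max_valid_epsilon` computes
that bound for the actual matrix rather than hard-coding a constant.
First-order perturbation theory gives the biased stationary state
``omega ~= omega0 + epsilon * omega1`` with an ``O(epsilon^2)`` error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .directions import UNIT_VECTORS, opposite
from .markov import (
    N_STATES,
    STATE_CURR,
    STATES,
    TransitionMatrix,
)
from .stationary import StationaryDistribution, solve_stationary

_UNIT_TOL = 1e-9


def coupling_coefficient(gamma: float, L: float, C: float, grad_c: float) -> float:
    """Dimensionless coupling ``epsilon = gamma * L * grad_c / C``.

    ``L`` is the typical cell size in micrometres (~10 for
    *Dictyostelium*), ``C`` the local chemoattractant concentration and
    ``grad_c`` its gradient magnitude (same concentration units per
    micrometre).  Only the *relative* steepness ``grad_c / C`` matters:
    scaling concentration and gradient together leaves epsilon fixed.
    """
    if C <= 0:
        raise ValueError(f"concentration C must be positive, got {C}")
    if L <= 0:
        raise ValueError(f"cell size L must be positive, got {L}")
    if grad_c < 0:
        raise ValueError(f"gradient magnitude must be nonnegative, got {grad_c}")
    return gamma * L * grad_c / C


@dataclass(frozen=True)
class CouplingParams:
    """Gradient coupling: strength ``epsilon`` and gradient direction."""

    epsilon: float
    gradient_direction: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be nonnegative, got {self.epsilon}")
        g = np.asarray(self.gradient_direction, dtype=float)
        if abs(np.linalg.norm(g) - 1.0) > _UNIT_TOL:
            raise ValueError(
                f"gradient_direction must be a unit vector, got {tuple(g)}"
            )
        object.__setattr__(self, "gradient_direction", (float(g[0]), float(g[1])))

    @classmethod
    def from_field(
        cls,
        gamma: float,
        C: float,
        grad_c: float,
        L: float = 10.0,
        gradient_direction: tuple[float, float] = (0.0, 1.0),
    ) -> "CouplingParams":
        """Build from the physical field parameters instead of epsilon."""
        return cls(coupling_coefficient(gamma, L, C, grad_c), gradient_direction)


def build_direction_coupling(
    gradient_direction: Sequence[float] = (0.0, 1.0),
) -> np.ndarray:
    """The epsilon-independent bias matrix ``Delta``.

    ``Delta[i, j] = g . n_hat(curr_j)`` on structurally allowed
    transitions whose target direction is not opposite to the current
    one; zero elsewhere.  Every row sums to zero exactly because the
    four biased targets pair up as opposite unit vectors.
    """
    g = np.asarray(gradient_direction, dtype=float)
    if abs(np.linalg.norm(g) - 1.0) > _UNIT_TOL:
        raise ValueError("gradient_direction must be a unit vector")
    coupling = UNIT_VECTORS @ g  # per target direction index - 1
    delta = np.zeros((N_STATES, N_STATES))
    for i, frm in enumerate(STATES):
        back = opposite(frm.curr)
        for j, to in enumerate(STATES):
            if to.prev != frm.curr or to.curr == back:
                continue
            delta[i, j] = coupling[to.curr - 1]
    return delta


def max_valid_epsilon(
    P0: TransitionMatrix,
    gradient_direction: Sequence[float] = (0.0, 1.0),
) -> float:
    """Largest coupling for which every biased entry stays in [0, 1].

    Scans all structurally biased entries: a negatively coupled entry
    caps epsilon at ``P0_ij / |g . n_hat_j|``, a positively coupled one
    at ``(1 - P0_ij) / (g . n_hat_j)``.  For the default parameters
    (``p = 1/7``, gradient along +y) the binding constraint is a de novo
    entry of weight ``p/3`` against the maximal coupling ``sqrt(3)/2``.
    """
    delta = build_direction_coupling(gradient_direction)
    bound = np.inf
    m = P0.entries
    neg = delta < -1e-15
    pos = delta > 1e-15
    if np.any(neg):
        bound = min(bound, np.min(m[neg] / -delta[neg]))
    if np.any(pos):
        bound = min(bound, np.min((1.0 - m[pos]) / delta[pos]))
    return float(bound)


def build_perturbed_matrix(
    P0: TransitionMatrix, coupling: CouplingParams
) -> TransitionMatrix:
    """Gradient-biased transition matrix ``P = P0 + epsilon * Delta``.

    Refuses couplings beyond the weak-coupling validity bound, where an
    entry would leave [0, 1].
    """
    eps = coupling.epsilon
    bound = max_valid_epsilon(P0, coupling.gradient_direction)
    if eps > bound:
        raise ValueError(
            f"epsilon={eps:g} exceeds the weak-coupling validity bound "
            f"{bound:.6g}; a transition probability would leave [0, 1]"
        )
    delta = build_direction_coupling(coupling.gradient_direction)
    return TransitionMatrix(P0.entries + eps * delta)


def perturbative_stationary(
    P0: TransitionMatrix,
    coupling: CouplingParams,
    delta: np.ndarray | None = None,
    order: int = 1,
) -> StationaryDistribution:
    """First-order stationary distribution of the biased chain.

    Solves ``omega1 (I - P0) = omega0 Delta`` on the subspace of
    zero-sum vectors (the correction carries no net probability) and
    returns ``omega0 + epsilon * omega1``.  The result matches the exact
    eigen-solution of the biased matrix up to ``O(epsilon^2)``.
    """
    if order != 1:
        raise NotImplementedError("only the first-order expansion is implemented")
    if delta is None:
        delta = build_direction_coupling(coupling.gradient_direction)
    omega0 = solve_stationary(P0)
    rhs = omega0.vector @ delta
    A = (np.eye(N_STATES) - P0.entries).T
    # Minimum-norm particular solution; the homogeneous solutions are
    # multiples of omega0, fixed below by the zero-sum condition.
    omega1, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    omega1 = omega1 - omega1.sum() * omega0.vector
    residual = np.max(np.abs(omega1 @ (np.eye(N_STATES) - P0.entries) - rhs))
    if residual > 1e-9:
        raise ValueError(
            f"projected perturbation system is singular (residual {residual:g}); "
            "is the unperturbed chain irreducible?"
        )
    return StationaryDistribution(omega0.vector + coupling.epsilon * omega1)


def stationary_mean_cos(
    omega: StationaryDistribution,
    gradient_direction: Sequence[float] = (0.0, 1.0),
) -> float:
    """Mean alignment ``<cos phi>`` of the current direction with the gradient.

    ``phi`` is the angle between the growing pseudopod and the gradient;
    the stationary average is ``sum_s omega(s) * g . n_hat(curr_s)``.
    Zero in a homogeneous medium, positive under an aligned bias, and it
    flips sign when the gradient is reversed.
    """
    g = np.asarray(gradient_direction, dtype=float)
    cos_per_state = UNIT_VECTORS[STATE_CURR - 1] @ g
    return float(omega.vector @ cos_per_state)
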