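"""Shared fixtures and independent oracles.

The brute-force transition oracle below evaluates the four two-step
scenarios (split-split, split-de novo, de novo-split, de novo-de novo)
literally as products of Kronecker deltas over the direction indices,
independently of the package's generative implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from dictywalk import ModelParams, PairState, build_transition_matrix
from dictywalk.markov import STATES


def _d(a: int, b: int) -> float:
    """Kronecker delta on direction labels, cyclic over 6."""
    return 1.0 if (a - b) % 6 == 0 else 0.0


def oracle_transition_prob(frm: PairState, to: PairState, params: ModelParams) -> float:
    """Literal delta-product evaluation of the four move scenarios."""
    p, a, b = params.p, params.alpha, params.beta
    m1, n1 = frm.prev, frm.curr
    m2, n2 = to.prev, to.curr
    chain = _d(m2, n1)  # the shared-direction constraint
    # split -> split
    ss = (1 - p) * chain * (
        _d(n2, n1 + 1) * (a * _d(n1, m1 + 1) + b * _d(n1, m1 - 1))
        + _d(n2, n1 - 1) * (b * _d(n1, m1 + 1) + a * _d(n1, m1 - 1))
    )
    wide_next = (1 - _d(n2, n1)) * (1 - _d(n2, n1 + 1)) * (1 - _d(n2, n1 - 1))
    wide_prev = (1 - _d(n1, m1)) * (1 - _d(n1, m1 + 1)) * (1 - _d(n1, m1 - 1))
    # split -> de novo
    sd = (p / 3) * chain * (_d(n1, m1 + 1) + _d(n1, m1 - 1)) * wide_next
    # de novo -> split
    ds = ((1 - p) / 2) * chain * (_d(n2, n1 + 1) + _d(n2, n1 - 1)) * wide_prev
    # de novo -> de novo
    dd = (p / 3) * chain * wide_prev * wide_next
    return ss + sd + ds + dd


def oracle_matrix(params: ModelParams) -> np.ndarray:
    return np.array(
        [[oracle_transition_prob(f, t, params) for t in STATES] for f in STATES]
    )


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()  # p = 1/7, alpha = 0.25, beta = 0.75


@pytest.fixture(scope="session")
def P0(default_params):
    return build_transition_matrix(default_params)
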