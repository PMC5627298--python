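"""The hexagonal direction lattice.

A pseudopod can extend along one of six equally spaced directions
``(n - 1) * pi / 3`` for ``n`` in 1..6, measured counterclockwise from a
fixed x-axis.  All geometry in the package is expressed through this
module so the direction convention lives in exactly one place.
"""

from __future__ import annotations

import numpy as np

N_DIRECTIONS = 6

_ANGLES = np.arange(N_DIRECTIONS) * np.pi / 3.0

#: Unit vectors of the six directions; row ``n - 1`` corresponds to index ``n``.
UNIT_VECTORS = np.column_stack([np.cos(_ANGLES), np.sin(_ANGLES)])
UNIT_VECTORS.setflags(write=False)


def angle(n: int) -> float:
    """Angle in radians of direction index ``n`` (1-based)."""
    _check_index(n)
    return float(_ANGLES[n - 1])


def unit_vector(n: int) -> np.ndarray:
    """Unit vector of direction index ``n`` (1-based)."""
    _check_index(n)
    return UNIT_VECTORS[n - 1]


def opposite(n: int) -> int:
    """Direction index pointing opposite to ``n`` (a pi turn)."""
    _check_index(n)
    return (n + 2) % N_DIRECTIONS + 1


def _check_index(n: int) -> None:
    if not (isinstance(n, (int, np.integer)) and 1 <= n <= N_DIRECTIONS):
        raise ValueError(f"direction index must be an integer in 1..6, got {n!r}")
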