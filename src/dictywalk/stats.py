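"""Motility statistics: MSD, persistent-random-walk fit, alignment, turns.

The mean-squared displacement of an ensemble is fitted to the Fürth
(persistent random walk) form

    <r^2(t)> = 2 v^2 [ tau t - tau^2 (1 - exp(-t / tau)) ],

which interpolates between ballistic motion (``t << tau``, MSD ~ v^2
t^2) and ordinary diffusion (``t >> tau``, MSD ~ 4 D t with
``D = v^2 tau / 2``).  ``v`` is the cell speed (um/min) and ``tau`` the
persistence time (min).

Chemotactic alignment is quantified by ``<cos phi>(t)``, the population
average of the cosine of the angle between the step direction and the
gradient, and by the chemotaxis index CI — the time average of
``<cos phi>`` after the initial transient — together with the standard
deviation across cells of each cell's own time-averaged alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.optimize

from .directions import UNIT_VECTORS
from .simulate import TrajectoryEnsemble


@dataclass(frozen=True)
class MsdCurve:
    """Ensemble-averaged squared displacement on the common time grid."""

    times_min: np.ndarray  # strictly positive grid
    msd_um2: np.ndarray
    n_realizations: int


@dataclass(frozen=True)
class FurthFit:
    v_um_per_min: float
    tau_min: float
    v_se: float
    tau_se: float
    fit_window_min: tuple[float, float]


def msd(ensemble: TrajectoryEnsemble) -> MsdCurve:
    """Squared displacement from the origin, averaged over realizations.

    This is a pure ensemble average — no time-lag averaging — so the
    curve at the first grid point equals the squared step length
    exactly (every first step has full length).
    """
    if ensemble.n_cells < 2:
        raise ValueError("MSD needs at least 2 trajectories to average over")
    disp = ensemble.positions - ensemble.positions[:, :1, :]
    sq = np.einsum("ntk,ntk->nt", disp, disp)
    return MsdCurve(
        times_min=ensemble.times_min[1:],
        msd_um2=sq.mean(axis=0)[1:],
        n_realizations=ensemble.n_cells,
    )


def diffusion_curve(curve: MsdCurve) -> np.ndarray:
    """Finite-time diffusion coefficient ``D(t) = MSD / (4 t)``, um^2/min."""
    return curve.msd_um2 / (4.0 * curve.times_min)


def furth_msd(t, v: float, tau: float):
    """Closed-form persistent-random-walk MSD."""
    t = np.asarray(t, dtype=float)
    return 2.0 * v**2 * (tau * t - tau**2 * (1.0 - np.exp(-t / tau)))


def fit_furth(
    curve: MsdCurve,
    fit_window_min: tuple[float, float] | None = None,
    weighting: str = "sqrt",
) -> FurthFit:
    """Nonlinear least-squares fit of the Fürth form to an MSD curve.

    Fitted on the linear scale over the full grid (or the given
    window).  The default ``weighting='sqrt'`` uses ``sigma
    proportional to sqrt(MSD)``: ensemble-MSD noise grows with the MSD
    itself, and the square-root compromise keeps both the ballistic and
    the diffusive regime informative instead of letting the noisiest
    large-time points dominate; ``'uniform'`` and ``'relative'``
    (``sigma proportional to MSD``) are available for sensitivity
    checks.  The initializer is deterministic — ``v0`` from the
    root-MSD slope at the first grid point, ``tau0 = 1`` min — so the
    fit is reproducible given the curve.  Standard errors come from the
    fit covariance.
    """
    t, y = curve.times_min, curve.msd_um2
    if fit_window_min is not None:
        lo, hi = fit_window_min
        keep = (t >= lo) & (t <= hi)
        t, y = t[keep], y[keep]
    else:
        fit_window_min = (float(t[0]), float(t[-1]))
    if len(t) < 3:
        raise ValueError("fit window contains fewer than 3 points")
    if np.all(y == 0):
        raise ValueError("degenerate MSD curve (identically zero)")
    if t[-1] < 10.0 * t[0]:
        raise ValueError(
            "MSD grid must span both the ballistic and the diffusive regime "
            "(largest time at least 10x the smallest)"
        )
    if weighting == "sqrt":
        sigma = np.sqrt(np.maximum(y, np.min(y[y > 0])))
    elif weighting == "relative":
        sigma = np.maximum(y, np.min(y[y > 0]))
    elif weighting == "uniform":
        sigma = None
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    v0 = float(np.sqrt(y[0]) / t[0])
    popt, pcov = scipy.optimize.curve_fit(
        furth_msd,
        t,
        y,
        p0=(v0, 1.0),
        sigma=sigma,
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        maxfev=10000,
    )
    se = np.sqrt(np.diag(pcov))
    return FurthFit(
        v_um_per_min=float(popt[0]),
        tau_min=float(popt[1]),
        v_se=float(se[0]),
        tau_se=float(se[1]),
        fit_window_min=fit_window_min,
    )


def _cos_phi_per_cell(
    ensemble: TrajectoryEnsemble, gradient_direction: Sequence[float]
) -> np.ndarray:
    g = np.asarray(gradient_direction, dtype=float)
    return UNIT_VECTORS[ensemble.directions - 1] @ g  # (n_cells, n_steps)


def mean_cos_phi(
    ensemble: TrajectoryEnsemble,
    gradient_direction: Sequence[float] = (0.0, 1.0),
) -> np.ndarray:
    """Population-averaged alignment ``<cos phi>`` at each step time."""
    return _cos_phi_per_cell(ensemble, gradient_direction).mean(axis=0)


def chemotaxis_index(
    ensemble: TrajectoryEnsemble,
    gradient_direction: Sequence[float] = (0.0, 1.0),
    transient_min: float = 2.0,
) -> tuple[float, float]:
    """Chemotaxis index and its across-cell standard deviation.

    CI is the time average of ``<cos phi>`` after discarding the first
    ``transient_min`` minutes (the alignment plateaus within a couple
    of minutes); the spread is the standard deviation over cells of
    each cell's own time-averaged cos phi.
    """
    cos = _cos_phi_per_cell(ensemble, gradient_direction)
    step_times = ensemble.times_min[1:]
    keep = step_times > transient_min
    if not np.any(keep):
        raise ValueError(
            f"transient cutoff {transient_min} min leaves no samples in a "
            f"{step_times[-1]:g}-min series"
        )
    per_cell = cos[:, keep].mean(axis=1)
    ci = float(per_cell.mean())
    ci_std = float(per_cell.std(ddof=1)) if len(per_cell) > 1 else float("nan")
    return ci, ci_std


def turn_statistics(ensemble: TrajectoryEnsemble) -> dict:
    """Handedness statistics of consecutive split-split move pairs.

    Among consecutive pairs of moves that are both splits, counts the
    same-handed combinations (LL, RR; L = counterclockwise) and the
    alternating ones (LR, RL), plus the number of consecutive pairs
    involving at least one de novo move.  The reported ratio
    ``(RL + LR) / (RR + LL)`` is ``None`` when no same-handed pair
    occurred (e.g. with splitting switched off entirely).
    """
    mt = ensemble.move_types  # 0 = ccw (L), 1 = cw (R), 2 = de novo
    a, b = mt[:, :-1], mt[:, 1:]
    both_split = (a < 2) & (b < 2)
    counts = {
        "LL": int(np.sum(both_split & (a == 0) & (b == 0))),
        "RR": int(np.sum(both_split & (a == 1) & (b == 1))),
        "LR": int(np.sum(both_split & (a == 0) & (b == 1))),
        "RL": int(np.sum(both_split & (a == 1) & (b == 0))),
        "denovo_involved": int(np.sum(~both_split)),
    }
    consecutive = counts["LL"] + counts["RR"]
    alternating = counts["LR"] + counts["RL"]
    counts["alternating_over_consecutive"] = (
        alternating / consecutive if consecutive > 0 else None
    )
    return counts
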