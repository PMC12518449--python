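"""Connects simulation output to the theory's predictions.

Shifts densities into the co-moving frame, measures the mass fraction near
each candidate concentration point, tracks moving candidates through time, and
compares the long-time total mass against ``-lambda_eps``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .fd_solver import PopulationState, SimulationResult

__all__ = [
    "ConcentrationReport",
    "RhoLimitReport",
    "comoving",
    "locate_mass",
    "track_mass_series",
    "rho_limit_check",
]

EXTINCTION_RHO = 1e-3


class WindowError(ValueError):
    """The co-moving window leaves the computational domain."""


@dataclass
class ConcentrationReport:
    time: float
    fractions: tuple[float, ...] | None
    dominant: int | None           # index into candidates, or None
    argmax_location: float
    rho: float
    extinct: bool


def comoving(state: PopulationState, c: float, epsilon: float,
             t: float | None = None) -> PopulationState:
    """Re-interpolate the density onto the frame ``x -> x - eps*c*t``.

    Linear interpolation; an error is raised when a non-negligible mass
    fraction would be shifted out of the domain.
    """
    if t is None:
        t = state.time
    shift = epsilon * c * t
    x = state.grid.nodes
    new_density = np.interp(x + shift, x, state.density, left=0.0, right=0.0)
    lost = state.rho - state.grid.dx * new_density.sum()
    if state.rho > 0 and lost > 1e-4 * state.rho + 1e-12:
        raise WindowError(
            f"co-moving shift {shift:.3g} pushes {lost:.3g} mass out of the domain")
    return PopulationState(density=new_density, time=state.time, grid=state.grid)


def locate_mass(state: PopulationState, candidates: Sequence[float],
                window: float, dominance_threshold: float = 0.5,
                extinction_rho: float = EXTINCTION_RHO) -> ConcentrationReport:
    """Mass fraction of the density within ``window`` of each candidate point."""
    rho = state.rho
    x = state.grid.nodes
    argmax_loc = float(x[np.argmax(state.density)])
    if rho < extinction_rho:
        return ConcentrationReport(time=state.time, fractions=None, dominant=None,
                                   argmax_location=argmax_loc, rho=rho, extinct=True)
    fracs = []
    for cand in candidates:
        mask = np.abs(x - cand) <= window
        fracs.append(float(state.grid.dx * state.density[mask].sum() / rho))
    dominant = None
    if fracs:
        k = int(np.argmax(fracs))
        if fracs[k] > dominance_threshold:
            dominant = k
    return ConcentrationReport(time=state.time, fractions=tuple(fracs),
                               dominant=dominant, argmax_location=argmax_loc,
                               rho=rho, extinct=False)


def track_mass_series(result: SimulationResult,
                      tracks: Sequence[Callable[[float], float]],
                      window: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-snapshot mass fractions around moving candidate tracks.

    ``tracks[k](t)`` gives the lab-frame position of candidate k at time t.
    Returns (times, fractions array of shape (n_snapshots, n_tracks)).
    """
    times = []
    rows = []
    for snap in result.snapshots:
        t = snap.time
        cands = [trk(t) for trk in tracks]
        rep = locate_mass(snap, cands, window, extinction_rho=0.0)
        times.append(t)
        rows.append(rep.fractions if rep.fractions is not None
                    else (np.nan,) * len(tracks))
    return np.array(times), np.array(rows)


@dataclass
class RhoLimitReport:
    rho_tail: float
    target: float            # -lambda_eps
    relative_gap: float
    tail_monotone: bool
    extinct: bool


def rho_limit_check(times: np.ndarray, rho: np.ndarray, lambda_eps: float,
                    tail_fraction: float = 0.1,
                    extinction_rho: float = EXTINCTION_RHO) -> RhoLimitReport:
    """Compare the tail-averaged total mass against ``-lambda_eps``.

    Requires at least 100 samples in the tail window.  For an extinct run
    (tail mass below the extinction threshold) the comparison is skipped.
    """
    times = np.asarray(times, dtype=float)
    rho = np.asarray(rho, dtype=float)
    n_tail = int(np.ceil(tail_fraction * len(rho)))
    if n_tail < 100:
        raise ValueError(
            f"tail window holds only {n_tail} samples; need >= 100")
    tail = rho[-n_tail:]
    rho_tail = float(tail.mean())
    if rho_tail < extinction_rho:
        return RhoLimitReport(rho_tail=rho_tail, target=-lambda_eps,
                              relative_gap=np.nan, tail_monotone=True,
                              extinct=True)
    target = -lambda_eps
    gap = abs(rho_tail - target) / abs(target) if target != 0 else np.inf
    drho = np.diff(tail)
    monotone = bool(np.all(drho >= -1e-10) or np.all(drho <= 1e-10))
    return RhoLimitReport(rho_tail=rho_tail, target=target, relative_gap=gap,
                          tail_monotone=monotone, extinct=False)
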