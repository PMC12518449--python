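"""Asymptotic-preserving scheme for the constrained Hamilton-Jacobi formulation.

Works with the phase ``u = -eps * log N`` of the co-moving density.  For
``eps > 0`` the update couples an upwind monotone Hamiltonian with the viscous
term and the non-local mass ``rho_n = dx * sum exp(-u/eps)``.  In the
``eps -> 0`` limit the mass is replaced by a scalar multiplier ``P_n`` chosen
each step so that the constraint ``min_i v_i = 0`` holds exactly; ``P_n`` is
the root of an affine-per-node function and has a closed form (a maximum over
nodes), cross-checked here by bisection.

The printed form of the discrete update has a ``dx^2`` denominator in the
forward slope of the Hamiltonian and ``dx`` under the viscous second
difference; both are dimensionally inconsistent and are treated as typos for
``dx`` and ``dx^2``.  ``paper_literal=True`` reproduces the printed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .fd_solver import TraitGrid
from .landscapes import FitnessLandscape

__all__ = [
    "HJState",
    "hamiltonian",
    "step_eps",
    "limit_multiplier",
    "step_limit",
    "run_eps",
    "run_limit",
    "NumericError",
    "ConstraintError",
]


class NumericError(RuntimeError):
    pass


class ConstraintError(RuntimeError):
    """The limit-scheme constraint ``min v = 0`` failed beyond tolerance."""


@dataclass
class HJState:
    """Phase vector with its associated mass (rho_n) or multiplier (P_n)."""

    phase: np.ndarray
    mass: float
    time: float
    grid: TraitGrid
    epsilon: float | None = None  # None marks the limit scheme

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.shape != (self.grid.nx,):
            raise ValueError("phase shape does not match grid")


def hamiltonian(p, q):
    """Monotone upwind Hamiltonian ``max{H+(p), H-(q)}``.

    ``H+(p) = p^2`` for ``p > 0`` (else 0), ``H-(q) = q^2`` for ``q < 0``
    (else 0).  Nondecreasing in ``p``, nonincreasing in ``q``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    hp = np.where(p > 0, p * p, 0.0)
    hm = np.where(q < 0, q * q, 0.0)
    return np.maximum(hp, hm)


def _slopes(u: np.ndarray, dx: float, c: float, paper_literal: bool = False):
    """Backward/forward difference quotients with c/2 offsets.

    The phase is extended by one ghost node on each side with linear
    extrapolation.
    """
    left = 2.0 * u[0] - u[1]
    right = 2.0 * u[-1] - u[-2]
    ext = np.concatenate([[left], u, [right]])
    backward = (ext[1:-1] - ext[:-2]) / dx - c / 2.0
    fwd_den = dx * dx if paper_literal else dx
    forward = (ext[2:] - ext[1:-1]) / fwd_den - c / 2.0
    return backward, forward, ext


def _mass(u: np.ndarray, dx: float, epsilon: float) -> float:
    """Overflow-guarded ``dx * sum exp(-u/eps)`` via log-sum-exp."""
    log_rho = logsumexp(-u / epsilon) + np.log(dx)
    if log_rho > 700.0:
        raise NumericError("mass overflow in exp(-u/eps); phase too negative")
    return float(np.exp(log_rho))


def step_eps(state: HJState, landscape: FitnessLandscape, grid: TraitGrid,
             dt: float, epsilon: float, c: float,
             paper_literal: bool = False) -> HJState:
    """One step of the eps > 0 scheme (frozen-frame landscape).

    ``u_new = u - dt*H(bw, fw) + dt*eps*lap - dt*(a(x) - c^2/4 - rho_n)``
    with ``rho_n`` the mass of the incoming state, then ``rho_{n+1}`` is
    recomputed from ``u_new``.
    """
    u = state.phase
    dx = grid.dx
    x = grid.nodes
    backward, forward, ext = _slopes(u, dx, c, paper_literal)
    h = hamiltonian(backward, forward)
    lap_den = dx if paper_literal else dx * dx
    lap = (ext[2:] - 2.0 * ext[1:-1] + ext[:-2]) / lap_den
    a_vals = landscape(x, 0.0)
    rho_n = state.mass
    u_new = u - dt * h + dt * epsilon * lap - dt * (a_vals - c * c / 4.0 - rho_n)
    if not np.all(np.isfinite(u_new)):
        raise NumericError("non-finite phase after eps-scheme step")
    rho_new = _mass(u_new, dx, epsilon)
    return HJState(phase=u_new, mass=rho_new, time=state.time + dt,
                   grid=grid, epsilon=epsilon)


def limit_multiplier(v: np.ndarray, grid: TraitGrid, landscape: FitnessLandscape,
                     dt: float, c: float, cross_check: bool = False) -> float:
    """The multiplier P making ``min_i v_i^{n+1} = 0`` after the limit update.

    The pre-update value at node i is affine in the trial multiplier J:
    ``pre_i(J) = v_i - dt*H_i - dt*(a_i - c^2/4 - J)`` with slope ``+dt``, so
    the unique root of ``J -> min_i pre_i(J)`` is the closed-form maximum
    ``P = max_i [ a_i - c^2/4 + H_i - v_i/dt ]``.
    """
    v = np.asarray(v, dtype=float)
    dx = grid.dx
    x = grid.nodes
    backward, forward, _ = _slopes(v, dx, c)
    h = hamiltonian(backward, forward)
    a_vals = landscape(x, 0.0)
    base = v - dt * h - dt * (a_vals - c * c / 4.0)  # pre_i(J) = base_i + dt*J
    p_closed = float(-base.min() / dt)
    if cross_check:
        lo = float(a_vals.min() - c * c / 4.0 - 1.0 - abs(base).max() / dt)
        hi = float(a_vals.max() - c * c / 4.0 + 1.0 + abs(base).max() / dt)
        from scipy.optimize import brentq

        def g(j):
            return float((base + dt * j).min())

        p_bis = brentq(g, lo, hi, xtol=1e-10)
        if abs(p_bis - p_closed) > 1e-8:
            raise NumericError(
                f"closed-form multiplier {p_closed} disagrees with bisection {p_bis}")
    return p_closed


def step_limit(state_or_v, grid: TraitGrid, landscape: FitnessLandscape,
               dt: float, c: float) -> HJState:
    """One step of the eps = 0 limit scheme; enforces ``min v = 0`` exactly."""
    if isinstance(state_or_v, HJState):
        v = state_or_v.phase
        t0 = state_or_v.time
    else:
        v = np.asarray(state_or_v, dtype=float)
        t0 = 0.0
    if v.min() < -1e-10 or v.min() > 1e-10:
        raise ConstraintError(f"incoming phase violates min v = 0: min = {v.min()}")
    dx = grid.dx
    x = grid.nodes
    backward, forward, _ = _slopes(v, dx, c)
    h = hamiltonian(backward, forward)
    a_vals = landscape(x, 0.0)
    p_new = limit_multiplier(v, grid, landscape, dt, c)
    v_new = v - dt * h - dt * (a_vals - c * c / 4.0 - p_new)
    m = v_new.min()
    if abs(m) > 1e-10:
        raise ConstraintError(f"min v after step = {m}, expected 0")
    v_new -= m  # pin the constraint to exact zero
    return HJState(phase=v_new, mass=p_new, time=t0 + dt, grid=grid, epsilon=None)


def default_dt(grid: TraitGrid, epsilon: float | None, slope_scale: float = 2.0,
               safety: float = 0.9) -> float:
    """Monotone-scheme step: gradient and viscous CFL combined.

    Requires ``dt*(2*eps/dx^2 + (|H_p| + |H_q|)/dx) <= 1`` with slopes up to
    ``slope_scale`` in each Hamiltonian argument.
    """
    rate = 4.0 * slope_scale / grid.dx
    if epsilon is not None and epsilon > 0:
        rate += 2.0 * epsilon / grid.dx**2
    return safety / rate


def run_eps(u0: np.ndarray, landscape: FitnessLandscape, grid: TraitGrid,
            epsilon: float, c: float, horizon: float, dt: float | None = None,
            snapshot_stride: int = 100) -> tuple[list[HJState], np.ndarray, np.ndarray]:
    """Iterate the eps-scheme to ``horizon``; returns snapshots, times, rho series."""
    if dt is None:
        dt = default_dt(grid, epsilon)
    nt = int(np.ceil(horizon / dt))
    state = HJState(phase=np.asarray(u0, dtype=float), mass=0.0, time=0.0,
                    grid=grid, epsilon=epsilon)
    state.mass = _mass(state.phase, grid.dx, epsilon)
    snaps = [state]
    masses = [state.mass]
    times = [0.0]
    for k in range(nt):
        state = step_eps(state, landscape, grid, dt, epsilon, c)
        masses.append(state.mass)
        times.append(state.time)
        if (k + 1) % snapshot_stride == 0 or k == nt - 1:
            snaps.append(state)
    return snaps, np.array(times), np.array(masses)


def run_limit(v0: np.ndarray, landscape: FitnessLandscape, grid: TraitGrid,
              c: float, horizon: float, dt: float | None = None,
              snapshot_stride: int = 100) -> tuple[list[HJState], np.ndarray, np.ndarray]:
    """Iterate the limit scheme; returns snapshots, times, P_n series."""
    if dt is None:
        dt = default_dt(grid, None)
    v0 = np.asarray(v0, dtype=float)
    v0 = v0 - v0.min()  # normalise the incoming constraint
    nt = int(np.ceil(horizon / dt))
    state = HJState(phase=v0, mass=np.nan, time=0.0, grid=grid, epsilon=None)
    snaps = [state]
    multipliers = [np.nan]
    times = [0.0]
    for k in range(nt):
        state = step_limit(state, grid, landscape, dt, c)
        multipliers.append(state.mass)
        times.append(state.time)
        if (k + 1) % snapshot_stride == 0 or k == nt - 1:
            snaps.append(state)
    return snaps, np.array(times), np.array(multipliers)
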