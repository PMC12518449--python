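"""Explicit finite-difference solver for the non-local selection-mutation PDE.

Solves ``dn/dt - eps^2 n_xx = n (a(x, t) - rho(t))`` on a truncated domain
``[0, L]`` with homogeneous Dirichlet boundaries, forward Euler in time and
centred second differences in space.  ``rho`` is the rectangle-rule total mass
and couples every trait through competition.

Two update modes are provided.  ``corrected`` (default) integrates the full
model: diffusion scaled by ``eps^2`` and the competition term ``-rho * n``
subtracted explicitly.  ``paper_literal`` reproduces the update exactly as
published (unscaled diffusion, growth term used verbatim) for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .landscapes import FitnessLandscape, InitialCondition

__all__ = [
    "TraitGrid",
    "TimeGrid",
    "PopulationState",
    "SimulationResult",
    "StabilityError",
    "DomainError",
    "cfl_bound",
    "step_explicit",
    "run",
]


class StabilityError(RuntimeError):
    """The explicit update blew up (CFL violated or dynamics too stiff)."""


class DomainError(ValueError):
    """The moving landscape support gets too close to the domain boundary."""


@dataclass(frozen=True)
class TraitGrid:
    """Uniform grid ``x_j = j*dx`` for ``j = 1..nx`` on ``(0, L]``."""

    length: float
    nx: int

    def __post_init__(self) -> None:
        if self.length <= 0 or self.nx < 3:
            raise ValueError("need length > 0 and nx >= 3")

    @property
    def dx(self) -> float:
        return self.length / self.nx

    @property
    def nodes(self) -> np.ndarray:
        return self.dx * np.arange(1, self.nx + 1)


@dataclass(frozen=True)
class TimeGrid:
    horizon: float
    nt: int

    def __post_init__(self) -> None:
        if self.horizon <= 0 or self.nt < 1:
            raise ValueError("need horizon > 0 and nt >= 1")

    @property
    def dt(self) -> float:
        return self.horizon / self.nt


@dataclass
class PopulationState:
    """Nonnegative density over the grid nodes at one time point."""

    density: np.ndarray
    time: float
    grid: TraitGrid

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.grid.nx,):
            raise ValueError("density shape does not match grid")

    @property
    def rho(self) -> float:
        """Rectangle-rule total mass ``dx * sum_j n_j``."""
        return float(self.grid.dx * self.density.sum())


def cfl_bound(grid: TraitGrid, epsilon: float, safety: float = 0.9) -> float:
    """Largest stable time step for the diffusion part: ``safety*dx^2/(2 eps^2)``."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return safety * grid.dx**2 / (2.0 * epsilon**2)


def stable_dt(grid: TraitGrid, epsilon: float, landscape: FitnessLandscape,
              rho_bound: float | None = None, safety: float = 0.9) -> float:
    """Positivity-preserving step: diffusion and reaction stiffness combined.

    Keeps ``1 - 2*dt*eps^2/dx^2 - dt*max|a - rho|`` nonnegative, so the
    forward-Euler update cannot drive the density negative.
    """
    lo, hi = landscape.support_interval(0.0)
    probe = np.linspace(lo - 2, hi + 2, 2001)
    vals = landscape(probe, 0.0)
    a_hi, a_lo = float(vals.max()), float(vals.min())
    if rho_bound is None:
        rho_bound = max(a_hi, 0.0) + 1.0
    reaction = max(abs(a_hi), abs(a_lo)) + rho_bound
    return safety / (2.0 * epsilon**2 / grid.dx**2 + reaction)


def step_explicit(state: PopulationState, landscape: FitnessLandscape,
                  grid: TraitGrid, dt: float, epsilon: float,
                  mode: str = "corrected",
                  comoving_c: float | None = None) -> PopulationState:
    """One forward-Euler step.  Boundary rows are held at zero.

    With ``comoving_c`` set, the landscape is frozen at t = 0 and the drift
    term ``eps*c*n_x`` is added with first-order upwind differencing (the
    co-moving-frame formulation).
    """
    n = state.density
    t_new = state.time + dt
    x = grid.nodes
    dx = grid.dx
    new = n.copy()
    lap = n[:-2] - 2.0 * n[1:-1] + n[2:]

    if mode == "corrected":
        if dt > cfl_bound(grid, epsilon, safety=1.0) * (1 + 1e-12):
            raise StabilityError(
                f"dt = {dt} exceeds the diffusion CFL bound "
                f"{cfl_bound(grid, epsilon, safety=1.0)}")
        rho = state.rho
        if comoving_c is None:
            a_vals = landscape(x[1:-1], t_new)
        else:
            a_vals = landscape(x[1:-1], 0.0)
        growth = n[1:-1] * (a_vals - rho)
        new[1:-1] = n[1:-1] + dt * epsilon**2 / dx**2 * lap + dt * growth
        if comoving_c is not None:
            c = comoving_c
            if c >= 0:  # information travels leftward: one-sided toward +x
                dn = (n[2:] - n[1:-1]) / dx
            else:
                dn = (n[1:-1] - n[:-2]) / dx
            new[1:-1] += dt * epsilon * c * dn
    elif mode == "paper_literal":
        # the printed update: no eps^2 factor, growth term a(x_j, t_{k+1})
        # taken verbatim (rho, if any, must be folded into the landscape)
        a_vals = landscape(x[1:-1], t_new)
        new[1:-1] = n[1:-1] + dt / dx**2 * lap + dt * n[1:-1] * a_vals
    else:
        raise ValueError(f"unknown mode {mode!r}")

    new[0] = 0.0
    new[-1] = 0.0
    if not np.all(np.isfinite(new)):
        raise StabilityError(
            "non-finite density after step; check dt against cfl_bound")
    if mode == "corrected" and new.min() < -1e-9 * max(new.max(), 1.0):
        raise StabilityError(
            "significantly negative density after step; check dt against cfl_bound")
    return PopulationState(density=new, time=t_new, grid=grid)


@dataclass
class SimulationResult:
    snapshots: list[PopulationState]
    snapshot_times: np.ndarray
    rho_times: np.ndarray
    rho: np.ndarray
    grid: TraitGrid
    epsilon: float

    @property
    def final(self) -> PopulationState:
        return self.snapshots[-1]

    def mass_table(self) -> np.ndarray:
        """(time, rho) two-column array for plain-text output."""
        return np.column_stack([self.rho_times, self.rho])


def _check_support_margin(landscape: FitnessLandscape, grid: TraitGrid,
                          horizon: float, margin: float = 5.0) -> None:
    lo0, hi0 = landscape.support_interval(0.0)
    loT, hiT = landscape.support_interval(horizon)
    lo, hi = min(lo0, loT), max(hi0, hiT)
    if lo < margin or hi > grid.length - margin:
        raise DomainError(
            f"landscape support [{lo:.3g}, {hi:.3g}] comes within {margin} trait "
            f"units of the domain [0, {grid.length}] during the run; enlarge the "
            "domain or shorten the horizon")


def run(landscape: FitnessLandscape, n0: InitialCondition | Callable,
        grid: TraitGrid, time_grid: TimeGrid, epsilon: float,
        mode: str = "corrected", snapshot_stride: int = 100,
        comoving_c: float | None = None,
        snapshot_times: Sequence[float] | None = None) -> SimulationResult:
    """Integrate the PDE and record snapshots plus the full mass series.

    The mass series is recorded at every step; snapshots every
    ``snapshot_stride`` steps (or at the requested ``snapshot_times``).
    """
    if mode == "corrected":
        _check_support_margin(landscape, grid, 0.0 if comoving_c is not None
                              else time_grid.horizon)
    dt = time_grid.dt
    x = grid.nodes
    density = np.asarray(n0(x), dtype=float)
    density[0] = 0.0
    density[-1] = 0.0
    state = PopulationState(density=density, time=0.0, grid=grid)

    want_times = None
    if snapshot_times is not None:
        want_times = sorted(float(t) for t in snapshot_times)

    snapshots = [state]
    rho_series = [state.rho]
    t_series = [0.0]
    next_want = 0
    for k in range(time_grid.nt):
        state = step_explicit(state, landscape, grid, dt, epsilon,
                              mode=mode, comoving_c=comoving_c)
        rho_series.append(state.rho)
        t_series.append(state.time)
        take = False
        if want_times is not None:
            while next_want < len(want_times) and state.time >= want_times[next_want] - dt / 2:
                take = True
                next_want += 1
        elif (k + 1) % snapshot_stride == 0:
            take = True
        if take or k == time_grid.nt - 1:
            snapshots.append(state)
    return SimulationResult(
        snapshots=snapshots,
        snapshot_times=np.array([s.time for s in snapshots]),
        rho_times=np.array(t_series),
        rho=np.array(rho_series),
        grid=grid,
        epsilon=epsilon,
    )
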