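"""Limiting Hamilton-Jacobi analysis: geodesic costs, phase construction, and
selection of concentration points.

The limiting phase between consecutive global maxima is the pointwise maximum
of an increasing and a decreasing branch, each an integral of the eikonal
speed ``sqrt(a_M - a)``.  Concentration candidates are the lagged optima; the
selected ones sit on the side with ``a'(x) > 0`` (for rightward shift), and the
refined subset attaches to the peaks with minimal curvature ``|a''|``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .landscapes import (
    AssumptionViolation,
    FitnessLandscape,
    LaggedOptimum,
    PeakInfo,
    global_maxima,
    lagged_optima,
)

__all__ = [
    "PhaseFunction",
    "ConcentrationPrediction",
    "geodesic_cost",
    "brute_force_cost",
    "build_phase",
    "concentration_points",
]


def _speed(landscape: FitnessLandscape, a_max: float):
    def f(s):
        val = a_max - np.asarray(landscape.frozen(s))
        if np.any(val < -1e-9):
            raise AssumptionViolation(
                f"a exceeds the supplied maximum a_M = {a_max} near {s}")
        return np.sqrt(np.maximum(val, 0.0))
    return f


def _quad_points(landscape: FitnessLandscape, lo: float, hi: float) -> list[float]:
    pts = []
    for comp in landscape.components:
        for edge in (comp.center - comp.support_half_width,
                     comp.center + comp.support_half_width,
                     comp.center):
            if lo < edge < hi:
                pts.append(edge)
    return sorted(pts)


def geodesic_cost(x: float, y: float, landscape: FitnessLandscape,
                  a_max: float | None = None) -> float:
    """Representation-formula cost ``-|int_x^y sqrt(a_M - a(s)) ds|`` (<= 0).

    In one dimension the optimal admissible path between two points is the
    monotone straight path, so the infimum reduces to this integral; adaptive
    quadrature with split points at bump support edges.
    """
    if a_max is None:
        a_max = global_maxima(landscape)[0].value
    if x == y:
        return 0.0
    lo, hi = min(x, y), max(x, y)
    f = _speed(landscape, a_max)
    val, _ = quad(f, lo, hi, points=_quad_points(landscape, lo, hi),
                  epsabs=1e-10, limit=200)
    return -abs(val)


def brute_force_cost(x: float, y: float, landscape: FitnessLandscape,
                     dx: float = 1e-3, a_max: float | None = None,
                     max_skip: int = 3) -> float:
    """Dynamic-programming oracle for :func:`geodesic_cost`.

    Minimises ``sum sqrt(a_M - a(z)) * |z_{k+1} - z_k|`` over monotone grid
    paths from x to y (steps of up to ``max_skip`` nodes), the integrand taken
    as the trapezoid average of the step's endpoints.  Negated so it is
    comparable to the formula.
    """
    if a_max is None:
        a_max = global_maxima(landscape)[0].value
    if x == y:
        return 0.0
    lo, hi = min(x, y), max(x, y)
    n = max(int(np.ceil((hi - lo) / dx)), 1)
    zs = np.linspace(lo, hi, n + 1)
    w = np.sqrt(np.maximum(a_max - np.asarray(landscape.frozen(zs)), 0.0))
    dp = np.full(n + 1, np.inf)
    dp[0] = 0.0
    for j in range(1, n + 1):
        lo_k = max(0, j - max_skip)
        ks = np.arange(lo_k, j)
        dp[j] = np.min(dp[ks] + 0.5 * (w[ks] + w[j]) * (zs[j] - zs[ks]))
    return -float(dp[-1])


@dataclass
class PhaseFunction:
    """Limiting phase on an interval between consecutive maxima."""

    xs: np.ndarray
    f1: np.ndarray        # decreasing branch from the left maximum
    f2: np.ndarray        # increasing branch toward the right maximum
    u: np.ndarray         # max{f1, f2}
    case: str             # "intersection" | "f1_only" | "f2_only"
    crossing: float | None
    c: float

    def eikonal_residual(self, landscape: FitnessLandscape,
                         a_max: float | None = None) -> np.ndarray:
        """``|u'| - sqrt(a_M - a)`` by central differences (kink nodes masked)."""
        if a_max is None:
            a_max = global_maxima(landscape)[0].value
        du = np.gradient(self.u, self.xs)
        target = np.sqrt(np.maximum(a_max - np.asarray(
            landscape.frozen(self.xs)), 0.0))
        res = np.abs(np.abs(du) - target)
        h = self.xs[1] - self.xs[0]
        if self.crossing is not None:
            res[np.abs(self.xs - self.crossing) <= 2 * h] = np.nan
        for comp in landscape.components:  # a' jumps at support edges
            for edge in (comp.center - comp.support_half_width,
                         comp.center + comp.support_half_width):
                res[np.abs(self.xs - edge) <= 2 * h] = np.nan
        res[0] = res[-1] = np.nan
        return res


def build_phase(landscape: FitnessLandscape, c: float,
                interval: tuple[float, float], u_left: float, u_right: float,
                n_points: int = 2001) -> PhaseFunction:
    """Construct ``u = max{f1, f2}`` between two consecutive maxima.

    ``f1(x) = u_left - int_{x_i}^{x} sqrt(a_M - a)`` and
    ``f2(x) = u_right - int_x^{x_{i+1}} sqrt(a_M - a)``; boundary values are
    taken as inputs (the limit problem does not fix the global constants).
    """
    x_i, x_ip1 = interval
    if x_i >= x_ip1:
        raise ValueError("interval must be increasing")
    a_max = global_maxima(landscape)[0].value
    xs = np.linspace(x_i, x_ip1, n_points)
    speed = np.sqrt(np.maximum(a_max - np.asarray(landscape.frozen(xs)), 0.0))
    # cumulative integral of the speed from x_i
    from scipy.integrate import cumulative_trapezoid
    big_f = np.concatenate([[0.0], cumulative_trapezoid(speed, xs)])
    f1 = u_left - big_f
    f2 = u_right - (big_f[-1] - big_f)
    u = np.maximum(f1, f2)
    diff = f1 - f2
    if np.all(diff >= 0):
        case, crossing = "f1_only", None
    elif np.all(diff <= 0):
        case, crossing = "f2_only", None
    else:
        k = int(np.argmax(diff < 0))
        # linear interpolation of the sign change
        x0, x1 = xs[k - 1], xs[k]
        d0, d1 = diff[k - 1], diff[k]
        crossing = float(x0 + (x1 - x0) * d0 / (d0 - d1))
        case = "intersection"
    return PhaseFunction(xs=xs, f1=f1, f2=f2, u=u, case=case,
                         crossing=crossing, c=c)


@dataclass
class ConcentrationPrediction:
    candidates: list[LaggedOptimum]
    selected: list[LaggedOptimum]
    shallowest: list[LaggedOptimum]
    peaks: list[PeakInfo]
    c: float

    def table(self) -> list[dict]:
        rows = []
        sel = {id(s) for s in self.selected}
        sha = {id(s) for s in self.shallowest}
        for cand in self.candidates:
            rows.append({
                "peak": cand.peak.location,
                "curvature": cand.peak.curvature_magnitude,
                "lagged_optimum": cand.location,
                "lagged_fitness": cand.lagged_fitness,
                "selected": id(cand) in sel,
                "shallowest": id(cand) in sha,
            })
        return rows


def concentration_points(landscape: FitnessLandscape, c: float,
                         fd_step: float = 1e-6) -> ConcentrationPrediction:
    """Candidate, selected, and curvature-refined concentration points.

    Candidates are the lagged optima; a candidate is selected when the
    landscape slope at it has the sign matching the shift direction
    (``a' > 0`` for ``c > 0``, mirrored for ``c < 0``; all candidates for
    ``c = 0``).  The refined subset keeps candidates of the peaks minimising
    ``|a''|`` among the global maxima.
    """
    peaks = global_maxima(landscape)
    candidates = lagged_optima(landscape, c)
    selected = []
    for cand in candidates:
        if c == 0:
            selected.append(cand)
            continue
        slope = float((landscape.frozen(cand.location + fd_step)
                       - landscape.frozen(cand.location - fd_step)) / (2 * fd_step))
        if (c > 0 and slope > 0) or (c < 0 and slope < 0):
            selected.append(cand)
    s_min = min(p.curvature_magnitude for p in peaks)
    shallow_locs = {p.location for p in peaks
                    if abs(p.curvature_magnitude - s_min) < 1e-12}
    shallowest = [cand for cand in selected if cand.peak.location in shallow_locs]
    return ConcentrationPrediction(candidates=candidates, selected=selected,
                                   shallowest=shallowest, peaks=peaks, c=c)
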