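"""Principal-eigenvalue machinery for the stationary persistence problems.

Discretises ``-eps^2 p'' - V(x) p = lambda p`` on a ball ``[x0 - R, x0 + R]``
with zero Dirichlet boundaries (centred second differences, symmetric
tridiagonal solve) and exposes the structure the persistence theory relies on:

* the Rayleigh-quotient monotonicity of ``lambda_R`` in R and its stabilised
  whole-line limit,
* the small-eps limit ``lambda_eps -> -(a_M - c^2/4)`` with the harmonic
  correction ``eps * sqrt(|a''|/2)``,
* the exact spectral equivalence between the drift eigenproblem and its
  symmetrised form via a diagonal (Liouville-type) similarity,
* exponential decay envelopes of the drift eigenvector, and
* the two-speed persistence classification by the minimal eigenvalue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import eigh_tridiagonal

from .landscapes import BumpComponent, FitnessLandscape, global_maxima

__all__ = [
    "EigenProblemSpec",
    "EigenPair",
    "PersistenceReport",
    "EpsilonLimitReport",
    "EnvelopeReport",
    "ResolutionError",
    "EigenSolveError",
    "principal_eigenpair_dirichlet",
    "principal_eigenpair_drift",
    "lambda_R_curve",
    "epsilon_limit_check",
    "decay_envelope_check",
    "persistence_classification",
    "mass_identity",
]


class ResolutionError(RuntimeError):
    """A structural monotonicity failed at the chosen discretisation."""


class EigenSolveError(RuntimeError):
    """The eigensolver produced a non-Perron (sign-changing) eigenvector."""


@dataclass
class EigenProblemSpec:
    """Symmetric Dirichlet ball problem ``-eps^2 p'' - V p = lambda p``.

    ``center`` defaults to the argmax of the potential (probed on a coarse
    grid); the ball is ``[center - radius, center + radius]``.  ``dx`` defaults
    to ``eps/10`` so the O(sqrt(eps)) eigenvector width is resolved.
    """

    potential: Callable[[np.ndarray], np.ndarray]
    epsilon: float
    radius: float
    center: float | None = None
    dx: float | None = None
    drift: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.radius <= 0:
            raise ValueError("epsilon and radius must be > 0")
        if self.dx is None:
            self.dx = self.epsilon / 10.0
        if self.center is None:
            probe = np.linspace(-100.0, 100.0, 40001)
            vals = np.asarray(self.potential(probe))
            self.center = float(probe[np.argmax(vals)])

    def interior_nodes(self) -> np.ndarray:
        m = int(round(2.0 * self.radius / self.dx))
        # keep dx exact by adjusting to an integer node count
        dx = 2.0 * self.radius / m
        return self.center - self.radius + dx * np.arange(1, m), dx


@dataclass
class EigenPair:
    eigenvalue: float
    eigenvector: np.ndarray
    nodes: np.ndarray
    dx: float
    normalization: str  # "L1_one" | "sup_one"
    provenance: str
    epsilon: float
    radius: float

    def to_sup_one(self) -> "EigenPair":
        vec = self.eigenvector / self.eigenvector.max()
        return EigenPair(self.eigenvalue, vec, self.nodes, self.dx,
                         "sup_one", self.provenance, self.epsilon, self.radius)

    def to_l1_one(self) -> "EigenPair":
        vec = self.eigenvector / (self.dx * self.eigenvector.sum())
        return EigenPair(self.eigenvalue, vec, self.nodes, self.dx,
                         "L1_one", self.provenance, self.epsilon, self.radius)


def _positive_perron(vec: np.ndarray) -> np.ndarray:
    if vec.sum() < 0:
        vec = -vec
    floor = -1e-12 * vec.max()
    if vec.min() < floor:
        raise EigenSolveError(
            f"eigenvector changes sign (min = {vec.min():.3g}); not the Perron mode")
    return np.clip(vec, 0.0, None)


def principal_eigenpair_dirichlet(spec: EigenProblemSpec) -> EigenPair:
    """Smallest eigenvalue + positive eigenvector of the symmetric ball problem."""
    if spec.drift != 0.0:
        raise ValueError("dirichlet solver requires drift = 0 (symmetric form)")
    nodes, dx = spec.interior_nodes()
    eps2 = spec.epsilon**2
    v = np.asarray(spec.potential(nodes), dtype=float)
    diag = 2.0 * eps2 / dx**2 - v
    off = np.full(len(nodes) - 1, -eps2 / dx**2)
    vals, vecs = eigh_tridiagonal(diag, off, select="i", select_range=(0, 0))
    vec = _positive_perron(vecs[:, 0])
    lam = float(vals[0])
    pair = EigenPair(lam, vec, nodes, dx, "raw", "dirichlet_ball",
                     spec.epsilon, spec.radius)
    return pair.to_l1_one()


def principal_eigenpair_drift(a: Callable[[np.ndarray], np.ndarray], c: float,
                              epsilon: float, radius: float,
                              center: float | None = None, dx: float | None = None,
                              method: str = "similarity") -> EigenPair:
    """Principal pair of ``-eps^2 p'' - eps*c*p' - a(x) p = lambda p``.

    ``similarity`` solves the symmetrised problem (potential ``a - c^2/4``) and
    maps the eigenvector by the diagonal scaling ``exp(-c x / (2 eps))``; the
    eigenvalue is unchanged exactly.  ``direct`` discretises the nonsymmetric
    operator with a centred first difference and extracts the eigenvalue of
    minimal real part by shift-invert.
    """
    def potential(x):
        return np.asarray(a(x)) - c * c / 4.0

    spec = EigenProblemSpec(potential=potential, epsilon=epsilon, radius=radius,
                            center=center, dx=dx)
    if method == "similarity":
        sym = principal_eigenpair_dirichlet(spec)
        # entries below the eigensolver's relative accuracy are noise; the
        # exponential similarity factor can amplify them by hundreds of orders
        # of magnitude, so zero them before mapping
        sym_vec = sym.eigenvector.copy()
        sym_vec[sym_vec < 1e-13 * sym_vec.max()] = 0.0
        with np.errstate(divide="ignore"):
            logp = np.log(sym_vec) - c * sym.nodes / (2.0 * epsilon)
        logp -= logp.max()
        vec = np.exp(logp)
        pair = EigenPair(sym.eigenvalue, vec, sym.nodes, sym.dx, "raw",
                         "drift_via_similarity", epsilon, radius)
        return pair.to_l1_one()
    if method == "direct":
        from scipy.sparse import diags
        from scipy.sparse.linalg import eigs

        nodes, h = spec.interior_nodes()
        eps2 = epsilon**2
        n = len(nodes)
        main = 2.0 * eps2 / h**2 - np.asarray(a(nodes), dtype=float)
        upper = np.full(n - 1, -eps2 / h**2 - epsilon * c / (2.0 * h))
        lower = np.full(n - 1, -eps2 / h**2 + epsilon * c / (2.0 * h))
        mat = diags([lower, main, upper], [-1, 0, 1], format="csc")
        sigma = float(-(np.asarray(a(nodes)).max() - c * c / 4.0) - 0.05)
        vals, vecs = eigs(mat, k=1, sigma=sigma)
        lam = vals[0]
        if abs(lam.imag) > 1e-8:
            raise EigenSolveError(f"complex principal eigenvalue {lam}")
        vec = vecs[:, 0]
        if abs(vec.imag).max() > 1e-8 * abs(vec.real).max():
            raise EigenSolveError("complex principal eigenvector")
        vec = _positive_perron(vec.real)
        pair = EigenPair(float(lam.real), vec, nodes, h, "raw", "drift_direct",
                         epsilon, radius)
        return pair.to_l1_one()
    raise ValueError(f"unknown method {method!r}")


def lambda_R_curve(spec: EigenProblemSpec, radii: Sequence[float],
                   tol: float = 1e-10) -> list[tuple[float, float]]:
    """``lambda_{R,eps}`` over increasing radii; asserts it is nonincreasing.

    All balls share the spec's center and dx so the discrete Rayleigh spaces
    are nested and the continuum monotonicity carries over exactly.
    """
    radii = list(radii)
    if any(radii[i] >= radii[i + 1] for i in range(len(radii) - 1)):
        raise ValueError("radii must be strictly increasing")
    out: list[tuple[float, float]] = []
    for r in radii:
        sub = EigenProblemSpec(potential=spec.potential, epsilon=spec.epsilon,
                               radius=r, center=spec.center, dx=spec.dx)
        pair = principal_eigenpair_dirichlet(sub)
        out.append((r, pair.eigenvalue))
    for (r1, l1), (r2, l2) in zip(out, out[1:]):
        if l2 > l1 + tol:
            raise ResolutionError(
                f"lambda({r2}) = {l2} > lambda({r1}) = {l1}: monotonicity in R "
                "violated; refine dx")
    return out


@dataclass
class EpsilonLimitReport:
    rows: list[tuple[float, float, float]]  # (eps, lambda, gap)
    limit: float                            # -(a_M - c^2/4)
    gaps_positive: bool
    gaps_decreasing: bool
    harmonic_bound_met: bool
    extinction_branch: bool


def epsilon_limit_check(landscape: FitnessLandscape, c: float,
                        epsilons: Sequence[float], radius: float) -> EpsilonLimitReport:
    """Track ``lambda_eps`` toward ``-(a_M - c^2/4)`` as eps decreases.

    The gap must be positive and decreasing, and the smallest-eps gap must sit
    under a generous harmonic envelope ``1.2*eps*sqrt(max(S_min, 0.5)/2)``
    where ``S_min`` is |a''| at the shallowest global maximum.
    """
    epsilons = list(epsilons)
    if any(epsilons[i] <= epsilons[i + 1] for i in range(len(epsilons) - 1)):
        raise ValueError("epsilons must be strictly decreasing")
    peaks = global_maxima(landscape)
    a_m = peaks[0].value
    s_min = min(p.curvature_magnitude for p in peaks)
    limit = -(a_m - c * c / 4.0)

    def potential(x):
        return np.asarray(landscape.frozen(x)) - c * c / 4.0

    rows = []
    for eps in epsilons:
        spec = EigenProblemSpec(potential=potential, epsilon=eps, radius=radius,
                                center=peaks[0].location)
        lam = principal_eigenpair_dirichlet(spec).eigenvalue
        rows.append((eps, lam, lam - limit))
    gaps = [g for _, _, g in rows]
    gaps_positive = all(g > 0 for g in gaps)
    gaps_decreasing = all(g2 < g1 for g1, g2 in zip(gaps, gaps[1:]))
    if not gaps_decreasing:
        raise ResolutionError(
            f"eigenvalue gaps not decreasing in eps: {gaps}; refine dx")
    eps_last = epsilons[-1]
    envelope = 1.2 * eps_last * np.sqrt(max(s_min, 0.5) / 2.0)
    harmonic_ok = gaps[-1] <= envelope
    return EpsilonLimitReport(rows=rows, limit=limit, gaps_positive=gaps_positive,
                              gaps_decreasing=gaps_decreasing,
                              harmonic_bound_met=harmonic_ok,
                              extinction_branch=(a_m - c * c / 4.0) < 0)


@dataclass
class EnvelopeReport:
    checked_nodes: int
    violations: int
    worst_log_margin: float
    kappa_lower: float
    kappa_upper: float


def decay_envelope_check(pair: EigenPair, landscape: FitnessLandscape, c: float,
                         epsilon: float, log_slack: float = 0.05) -> EnvelopeReport:
    """Check the exponential decay envelopes of the sup-normalised eigenvector.

    With distances measured from the support midpoint, verifies
    ``exp(-k_low*|x - x_peak|/eps) <= p <= min(1, exp(-k_up*(|x| - R0)/eps))``
    at nodes beyond ``R0 + 1``, where ``k_up = (sqrt(a_M) + c)/2`` and
    ``k_low = c/2 + 2*sqrt(|a_m + lambda - c^2/4|)`` (evaluated as printed).
    Nodes where the eigenvector has underflowed below 1e-250, and nodes in the
    outer 10% of the ball (Dirichlet boundary layer), are excluded.  Violations
    are reported with ``log_slack`` relative slack on the log scale.
    """
    p = pair.to_sup_one()
    lo, hi = landscape.support_interval(0.0)
    mid = 0.5 * (lo + hi)
    r0 = 0.5 * (hi - lo)
    peaks = global_maxima(landscape)
    a_max = peaks[0].value
    probe = np.linspace(lo - 2, hi + 2, 4001)
    a_min = float(np.min(landscape.frozen(probe)))
    lam = pair.eigenvalue
    k_up = (np.sqrt(max(a_max, 0.0)) + c) / 2.0
    k_low = c / 2.0 + 2.0 * np.sqrt(abs(a_min + lam - c * c / 4.0))

    x = p.nodes
    vec = p.eigenvector
    x_peak = float(x[np.argmax(vec)])
    dist_mid = np.abs(x - mid)
    ball_lo, ball_hi = x[0], x[-1]
    margin = 0.1 * (ball_hi - ball_lo)
    interior = (x > ball_lo + margin) & (x < ball_hi - margin)
    far = dist_mid > r0 + 1.0
    with np.errstate(divide="ignore"):
        logp = np.where(vec > 0, np.log(np.maximum(vec, 1e-300)), -np.inf)
    log_upper = np.minimum(0.0, -k_up * (dist_mid - r0) / epsilon)
    log_lower = -k_low * np.abs(x - x_peak) / epsilon
    usable = far & interior & (vec > 1e-250) & (log_lower > -500.0)

    slack = log_slack * np.maximum(np.abs(log_upper), np.abs(log_lower)) + 1e-6
    upper_viol = logp[usable] > log_upper[usable] + slack[usable]
    lower_viol = logp[usable] < log_lower[usable] - slack[usable]
    nviol = int(upper_viol.sum() + lower_viol.sum())
    margins = np.concatenate([
        (log_upper[usable] - logp[usable]),
        (logp[usable] - log_lower[usable]),
    ]) if usable.any() else np.array([0.0])
    return EnvelopeReport(checked_nodes=int(usable.sum()), violations=nviol,
                          worst_log_margin=float(margins.min()),
                          kappa_lower=float(k_low), kappa_upper=float(k_up))


@dataclass
class PersistenceReport:
    lambda1: float
    lambda2: float
    verdict: str  # "persists" | "extinct"
    dominant_index: int | None
    lagged_fitnesses: tuple[float, float]
    epsilon: float
    limit_lambdas: tuple[float, float] = field(default=(np.nan, np.nan))


def persistence_classification(a1: BumpComponent, a2: BumpComponent,
                               c1: float, c2: float, d: float, epsilon: float,
                               radius: float) -> PersistenceReport:
    """Two-speed persistence verdict from the minimal principal eigenvalue.

    ``lambda_i`` solves the symmetric ball problem with potential
    ``a_i(x) - c_i^2/4 - d``.  Extinct iff ``min(lambda_1, lambda_2) >= 0``;
    otherwise the population persists following the track with the minimal
    eigenvalue.  Ties (within 1e-6) leave the dominant index undetermined.
    """
    if not (c1 < 0 < c2):
        warnings.warn(f"case-2 assumption c1 < 0 < c2 violated: ({c1}, {c2})",
                      stacklevel=2)
    lams = []
    for comp, c in ((a1, c1), (a2, c2)):
        def potential(x, comp=comp, c=c):
            return np.asarray(comp(x)) - c * c / 4.0 - d

        spec = EigenProblemSpec(potential=potential, epsilon=epsilon,
                                radius=radius, center=comp.center)
        lams.append(principal_eigenpair_dirichlet(spec).eigenvalue)
    lam1, lam2 = lams
    lagged = (a1.height - c1 * c1 / 4.0 - d, a2.height - c2 * c2 / 4.0 - d)
    limit_lams = (-lagged[0], -lagged[1])
    verdict = "extinct" if min(lam1, lam2) >= 0 else "persists"
    if abs(lam1 - lam2) < 1e-6:
        dominant = None
    else:
        dominant = 1 if lam1 < lam2 else 2
    # cross-check the ordering against the eps -> 0 closed form
    if dominant is not None and limit_lams[0] != limit_lams[1]:
        dominant0 = 1 if limit_lams[0] < limit_lams[1] else 2
        if dominant0 != dominant:
            warnings.warn(
                "finite-eps eigenvalue ordering disagrees with the eps->0 "
                "closed form: eps may be too large for the asymptotic regime",
                stacklevel=2)
    return PersistenceReport(lambda1=lam1, lambda2=lam2, verdict=verdict,
                             dominant_index=dominant, lagged_fitnesses=lagged,
                             epsilon=epsilon, limit_lambdas=limit_lams)


def mass_identity(a: Callable[[np.ndarray], np.ndarray], pair: EigenPair) -> float:
    """``integral a * p`` for an L1-normalised eigenvector (equals -lambda)."""
    p = pair.to_l1_one()
    return float(p.dx * np.sum(np.asarray(a(p.nodes)) * p.eigenvector))
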