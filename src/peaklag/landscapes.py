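"""Fitness landscapes built from compactly supported polynomial bumps.

A landscape is a sum of shifted bump components ``(h - (x - x0)^p)^+`` minus a
constant death rate.  Each component may translate in time at its own speed
``c`` (the trait-space position of the bump at time ``t`` is ``x0 + eps*c*t``).
The module also extracts the structural quantities the long-time theory needs:
global maxima with their curvatures, and the *lagged optima* -- the points
``x`` with ``a(x) = a_M - c^2/4`` on the side where ``a'(x) > 0`` (for ``c > 0``)
at which a population tracking a moving peak concentrates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ParameterError",
    "AssumptionViolation",
    "BumpComponent",
    "FitnessLandscape",
    "PeakInfo",
    "LaggedOptimum",
    "InitialCondition",
    "AssumptionReport",
    "CASE1",
    "CASE2",
    "make_bump",
    "compose_landscape",
    "validate_assumptions",
    "global_maxima",
    "lagged_optima",
    "component_lagged_optimum",
    "gaussian_initial_condition",
    "preset",
    "PRESET_NAMES",
]

CASE1 = "case1_common_speed"
CASE2 = "case2_diverging"

#: absolute x-tolerance for all bracketed root-finding in this module
ROOT_XTOL = 1e-10


class ParameterError(ValueError):
    """Invalid construction parameter (e.g. odd bump exponent)."""


class AssumptionViolation(RuntimeError):
    """A structural assumption required by the theory fails."""


@dataclass(frozen=True)
class BumpComponent:
    """One compactly supported bump ``(height - (x - center)^exponent)^+``.

    ``shift_speed`` is the speed ``c`` of the bump in rescaled time: at time
    ``t`` the bump is centred at ``center + eps*c*t`` (``eps`` lives on the
    enclosing landscape).
    """

    center: float
    height: float
    exponent: int
    shift_speed: float = 0.0

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ParameterError(f"bump height must be > 0, got {self.height}")
        if self.exponent < 2 or self.exponent % 2 != 0:
            raise ParameterError(
                f"bump exponent must be an even integer >= 2, got {self.exponent}"
            )

    @property
    def support_half_width(self) -> float:
        """Half-width of the support: root of ``height - w^exponent = 0``."""
        return self.height ** (1.0 / self.exponent)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        val = self.height - (x - self.center) ** self.exponent
        return np.maximum(val, 0.0)

    def derivative(self, x):
        """One-sided-consistent first derivative (0 outside the open support)."""
        x = np.asarray(x, dtype=float)
        inside = np.abs(x - self.center) < self.support_half_width
        d = -self.exponent * (x - self.center) ** (self.exponent - 1)
        return np.where(inside, d, 0.0)

    def second_derivative(self, x):
        """Second derivative inside the open support, 0 outside."""
        x = np.asarray(x, dtype=float)
        inside = np.abs(x - self.center) < self.support_half_width
        p = self.exponent
        if p == 2:
            d2 = np.full_like(x, -2.0)
        else:
            d2 = -p * (p - 1) * (x - self.center) ** (p - 2)
        return np.where(inside, d2, 0.0)


def make_bump(center: float, height: float, exponent: int, shift_speed: float = 0.0) -> BumpComponent:
    """Construct a bump component, validating the exponent and height."""
    return BumpComponent(center=float(center), height=float(height),
                         exponent=int(exponent), shift_speed=float(shift_speed))


@dataclass
class FitnessLandscape:
    """Sum of (possibly moving) bumps minus a constant death rate.

    Evaluation: ``a(x, t) = sum_i b_i(x - eps*c_i*t) - d``.
    """

    components: tuple[BumpComponent, ...]
    death_rate: float
    case_tag: str
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        self.components = tuple(self.components)
        if not self.components:
            raise ParameterError("landscape needs at least one bump component")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be > 0")
        speeds = sorted({c.shift_speed for c in self.components})
        if self.case_tag == CASE1:
            if len(speeds) != 1:
                raise AssumptionViolation(
                    f"{CASE1} requires a single common shift speed, got {speeds}"
                )
        elif self.case_tag == CASE2:
            neg = [s for s in speeds if s < 0]
            pos = [s for s in speeds if s > 0]
            if len(neg) != 1 or len(pos) != 1 or len(speeds) != 2:
                raise AssumptionViolation(
                    "case2 requires exactly two speeds with c1 < 0 < c2, "
                    f"got {speeds}"
                )
        else:
            raise ParameterError(f"unknown case_tag {self.case_tag!r}")
        if self.death_rate <= 0:
            warnings.warn(
                "death rate d <= 0: the model declares d a positive constant; "
                "accepting the value as given",
                stacklevel=3,
            )

    # -- structure ---------------------------------------------------------

    @property
    def speeds(self) -> tuple[float, ...]:
        return tuple(c.shift_speed for c in self.components)

    @property
    def common_speed(self) -> float:
        if self.case_tag != CASE1:
            raise AssumptionViolation("common_speed is only defined for case 1")
        return self.components[0].shift_speed

    @property
    def speed_pair(self) -> tuple[float, float]:
        if self.case_tag != CASE2:
            raise AssumptionViolation("speed_pair is only defined for case 2")
        speeds = sorted({c.shift_speed for c in self.components})
        return speeds[0], speeds[1]

    def support_interval(self, t: float = 0.0) -> tuple[float, float]:
        """Smallest closed interval containing every component support at time t."""
        lo = min(c.center + self.epsilon * c.shift_speed * t - c.support_half_width
                 for c in self.components)
        hi = max(c.center + self.epsilon * c.shift_speed * t + c.support_half_width
                 for c in self.components)
        return lo, hi

    @property
    def support_radius(self) -> float:
        """R0: smallest radius with ``a(x) = -d`` (hence < -d') for |x| > R0 at t=0."""
        lo, hi = self.support_interval(0.0)
        return max(abs(lo), abs(hi))

    # -- evaluation --------------------------------------------------------

    def __call__(self, x, t: float = 0.0):
        x = np.asarray(x, dtype=float)
        total = np.zeros_like(x)
        for c in self.components:
            total = total + c(x - self.epsilon * c.shift_speed * t)
        return total - self.death_rate

    def frozen(self, x):
        """The landscape at t = 0 (the frozen / co-moving frame for case 1)."""
        return self(x, 0.0)

    def frozen_derivative(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c in self.components:
            out = out + c.derivative(x)
        return out

    def frozen_second_derivative(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c in self.components:
            out = out + c.second_derivative(x)
        return out


def compose_landscape(components: Sequence[BumpComponent], d: float,
                      case_tag: str = CASE1, epsilon: float = 0.1) -> FitnessLandscape:
    """Assemble a landscape ``sum_i b_i(x - eps*c_i*t) - d`` from bumps."""
    return FitnessLandscape(components=tuple(components), death_rate=float(d),
                            case_tag=case_tag, epsilon=float(epsilon))


# ---------------------------------------------------------------------------
# Maxima / curvature extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakInfo:
    """A global maximum of the frozen landscape."""

    location: float
    value: float
    curvature_magnitude: float  # |a''| at the peak (0 for quartic-topped bumps)


@dataclass(frozen=True)
class LaggedOptimum:
    """A point x̄ with ``a(x̄) = a_M - c^2/4`` on the selected side of a peak."""

    location: float
    lagged_fitness: float
    peak: PeakInfo


def _peak_candidates(landscape: FitnessLandscape) -> list[float]:
    # Bump maxima sit at component centers unless supports overlap; refine each
    # candidate on a local grid to cover the overlapping case.
    cands = []
    for comp in landscape.components:
        x0 = comp.center
        w = comp.support_half_width
        grid = np.linspace(x0 - w, x0 + w, 4001)
        vals = landscape.frozen(grid)
        j = int(np.argmax(vals))
        v_center = float(landscape.frozen(x0))
        if vals[j] <= v_center + 1e-12:
            # the component center is the local argmax (isolated bump)
            cands.append(x0)
            continue
        # overlapping supports shift the maximum: refine around the coarse argmax
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        fine = np.linspace(lo, hi, 2001)
        fv = landscape.frozen(fine)
        cands.append(float(fine[np.argmax(fv)]))
    return cands


def global_maxima(landscape: FitnessLandscape, tol: float = 1e-8) -> list[PeakInfo]:
    """Locate the global maxima of the frozen landscape with their |a''|.

    Raises :class:`AssumptionViolation` if a maximum is non-isolated (flat top).
    """
    cands = _peak_candidates(landscape)
    values = [float(landscape.frozen(x)) for x in cands]
    a_m = max(values)
    peaks: list[PeakInfo] = []
    for x, v in zip(cands, values):
        if v >= a_m - tol:
            if any(abs(x - p.location) < 1e-6 for p in peaks):
                continue
            curv = abs(float(landscape.frozen_second_derivative(x)))
            peaks.append(PeakInfo(location=x, value=a_m, curvature_magnitude=curv))
    peaks.sort(key=lambda p: p.location)
    # flat-top detection: the landscape must drop off a short distance from
    # each reported maximum
    for p in peaks:
        off = landscape.frozen(np.array([p.location - 0.05, p.location + 0.05]))
        if np.all(off >= a_m - 1e-12):
            raise AssumptionViolation(
                f"non-isolated maximum near x = {p.location}: flat top detected"
            )
    return peaks


# ---------------------------------------------------------------------------
# Lagged optima
# ---------------------------------------------------------------------------

def _left_crossing(f: Callable[[float], float], x_peak: float, x_far: float) -> float:
    """Root of f in (x_far, x_peak) nearest x_peak, via scan + brentq."""
    n = 400
    xs = np.linspace(x_peak, x_far, n)
    fv = np.array([f(x) for x in xs])
    for k in range(1, n):
        if fv[k] <= 0.0 < fv[k - 1] or (fv[k] < 0.0 <= fv[k - 1]):
            return float(brentq(f, xs[k], xs[k - 1], xtol=ROOT_XTOL))
    raise AssumptionViolation(
        "no level crossing found where assumption (A5) guarantees one "
        f"(searched ({x_far}, {x_peak}))"
    )


def lagged_optima(landscape: FitnessLandscape, c: float) -> list[LaggedOptimum]:
    """The lagged optimum behind each global maximum for shift speed ``c``.

    For ``c > 0`` the crossing with ``a'(x̄) > 0`` just left of each peak; the
    mirror side for ``c < 0``; the peaks themselves for ``c = 0``.  Empty when
    the level ``a_M - c^2/4`` falls below the off-support value ``-d``.
    """
    peaks = global_maxima(landscape)
    a_m = peaks[0].value
    level = a_m - c * c / 4.0
    if level <= float(landscape.frozen(landscape.support_interval()[0] - 1.0)):
        return []

    def g(x: float) -> float:
        return float(landscape.frozen(x)) - level

    out: list[LaggedOptimum] = []
    lo_sup, hi_sup = landscape.support_interval()
    for i, p in enumerate(peaks):
        if c == 0.0:
            out.append(LaggedOptimum(p.location, level, p))
            continue
        if c > 0:
            far = peaks[i - 1].location if i > 0 else lo_sup - 1.0
            x_bar = _left_crossing(g, p.location, far)
        else:
            far = peaks[i + 1].location if i + 1 < len(peaks) else hi_sup + 1.0
            x_bar = _left_crossing(g, p.location, far)
        out.append(LaggedOptimum(x_bar, level, p))
    return out


def component_lagged_optimum(component: BumpComponent, c: float, d: float = 0.0) -> float:
    """Lagged optimum of a single bump tracked at speed ``c`` (frame of the bump).

    Solves ``b(x) = b_M - c^2/4`` on the trailing side (left for c > 0, right
    for c < 0).  ``d`` only shifts fitness, not the location.
    """
    del d  # location is independent of the death rate
    if c == 0.0:
        return component.center
    level = component.height - c * c / 4.0
    if level <= 0.0:
        raise AssumptionViolation(
            f"no lagged optimum: height - c^2/4 = {level} <= 0 (bump overrun)"
        )
    offset = (component.height - level) ** (1.0 / component.exponent)
    return component.center - offset if c > 0 else component.center + offset


# ---------------------------------------------------------------------------
# Initial conditions
# ---------------------------------------------------------------------------

@dataclass
class InitialCondition:
    """Continuous nonnegative initial density bounded by ``exp(C1 - C2|x|)``."""

    evaluator: Callable[[np.ndarray], np.ndarray]
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ParameterError("decay constants C1, C2 must be > 0")

    def __call__(self, x):
        return np.asarray(self.evaluator(np.asarray(x, dtype=float)), dtype=float)

    def check_envelope(self, x: np.ndarray) -> bool:
        vals = self(x)
        env = np.exp(self.c1 - self.c2 * np.abs(x))
        return bool(np.all(vals >= 0) and np.all(vals <= env + 1e-12))


def gaussian_initial_condition(center: float = 37.5, amplitude: float = 0.1,
                               width: float = 10.0) -> InitialCondition:
    """The figure-style initial density ``amplitude * exp(-(x-center)^2/width^2)``."""

    def n0(x):
        return amplitude * np.exp(-((x - center) ** 2) / width**2)

    # envelope constants: e^{C1 - C2|x|} dominates the gaussian for C2 = 1 and
    # C1 = |center| + log(amplitude) + width^2/4 + margin
    c1 = abs(center) + math.log(max(amplitude, 1e-12)) + width**2 / 4.0 + 1.0
    return InitialCondition(evaluator=n0, c1=c1, c2=1.0)


# ---------------------------------------------------------------------------
# Assumption validation
# ---------------------------------------------------------------------------

@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str
    locations: tuple[float, ...] = ()


@dataclass
class AssumptionReport:
    checks: dict[str, CheckResult] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks.values())

    def __getitem__(self, name: str) -> CheckResult:
        return self.checks[name]


def _crossings(xs: np.ndarray, fv: np.ndarray) -> list[float]:
    roots = []
    for k in range(1, len(xs)):
        if fv[k - 1] == 0.0:
            roots.append(float(xs[k - 1]))
        elif fv[k - 1] * fv[k] < 0.0:
            roots.append(float(xs[k - 1] + (xs[k] - xs[k - 1])
                               * fv[k - 1] / (fv[k - 1] - fv[k])))
    return roots


def validate_assumptions(landscape: FitnessLandscape, c_or_pair) -> AssumptionReport:
    """Probe-grid checks of the structural assumptions behind the theory.

    Checks boundedness, confinement beyond the support radius, finitely many
    ordered maxima, and the exact level-crossing counts of the lagged-fitness
    level in each inter-peak and outer interval.  Failures are reported, not
    raised.
    """
    report = AssumptionReport()
    warns: list[str] = []
    d = landscape.death_rate
    if d <= 0:
        warns.append("death rate d <= 0 (model declares d positive); accepted as given")

    r0 = landscape.support_radius
    lo, hi = landscape.support_interval()
    probe = np.linspace(lo - 5.0, hi + 5.0, 20001)
    vals = landscape.frozen(probe)

    # (A1): confinement -- a < -d' beyond the support for some d' > 0.  When
    # d <= 0 (accepted as given for some presets, flagged above) the literal
    # bound cannot hold; the structural content checked is that the bump part
    # vanishes identically off-support, i.e. a == -d there.
    outside = (probe < lo) | (probe > hi)
    sup_out = float(vals[outside].max()) if outside.any() else -d
    if d > 0:
        a1_ok = sup_out < 0.0
    else:
        a1_ok = sup_out <= -d + 1e-12
    report.checks["A1_confinement"] = CheckResult(
        "A1_confinement", a1_ok,
        f"sup a outside support = {sup_out:.6g} (R0 = {r0:.6g}, d = {d:g})")

    # (A2): finite max and min
    a_max, a_min = float(vals.max()), float(vals.min())
    report.checks["A2_bounded"] = CheckResult(
        "A2_bounded", np.isfinite(a_max) and np.isfinite(a_min),
        f"max = {a_max:.6g}, min = {a_min:.6g}")

    # (A4)/(B4): finitely many global maxima, strictly ordered
    try:
        peaks = global_maxima(landscape)
        ordered = all(peaks[i].location < peaks[i + 1].location
                      for i in range(len(peaks) - 1))
        report.checks["A4_finite_maxima"] = CheckResult(
            "A4_finite_maxima", ordered and len(peaks) >= 1,
            f"{len(peaks)} global maxima",
            tuple(p.location for p in peaks))
    except AssumptionViolation as exc:
        report.checks["A4_finite_maxima"] = CheckResult(
            "A4_finite_maxima", False, str(exc))
        report.warnings = tuple(warns)
        return report

    # (A5)/(B5): level-crossing counts of a = a_M - c^2/4
    if landscape.case_tag == CASE1:
        speeds = [float(c_or_pair)]
        groups = [landscape.components]
        peak_sets = [peaks]
    else:
        c1, c2 = (float(v) for v in c_or_pair)
        speeds = [c1, c2]
        groups = [tuple(c for c in landscape.components if c.shift_speed < 0),
                  tuple(c for c in landscape.components if c.shift_speed > 0)]
        peak_sets = [None, None]

    for tag, (speed, comps, pset) in enumerate(zip(speeds, groups, peak_sets), start=1):
        if landscape.case_tag == CASE1:
            a_of = landscape.frozen
            a_m = peaks[0].value
            locs = [p.location for p in pset]
        else:
            def a_of(x, comps=comps):
                x = np.asarray(x, dtype=float)
                out = np.zeros_like(x)
                for comp in comps:
                    out = out + comp(x)
                return out - d
            a_m = max(float(a_of(comp.center)) for comp in comps)
            locs = sorted(comp.center for comp in comps)
        level = a_m - speed * speed / 4.0
        name = "A5_level_crossings" if landscape.case_tag == CASE1 else f"B5_level_crossings_{tag}"
        fv = np.asarray(a_of(probe)) - level
        ok = True
        details = []
        found: list[float] = []
        # inner intervals: exactly two crossings each
        for i in range(1, len(locs)):
            seg = (probe > locs[i - 1]) & (probe < locs[i])
            roots = _crossings(probe[seg], fv[seg])
            found.extend(roots)
            if len(roots) != 2:
                ok = False
            details.append(f"({locs[i-1]:.4g},{locs[i]:.4g}): {len(roots)} crossings")
        # outer interval on the trailing side: exactly one crossing
        if speed >= 0:
            seg = probe < locs[0]
        else:
            seg = probe > locs[-1]
        roots = _crossings(probe[seg], fv[seg])
        found.extend(roots)
        if len(roots) != 1:
            ok = False
        details.append(f"outer: {len(roots)} crossings")
        report.checks[name] = CheckResult(
            name, ok, f"level {level:.6g}; " + "; ".join(details), tuple(found))

    report.warnings = tuple(warns)
    return report


# ---------------------------------------------------------------------------
# Presets (named experiment parameter sets)
# ---------------------------------------------------------------------------

PRESET_NAMES = ("fig4", "fig5", "fig6", "fig7", "fig8")


def preset(name: str, **overrides) -> dict:
    """Return the parameter set of a named reference experiment.

    The returned dict holds a :class:`FitnessLandscape`, the initial density,
    epsilon, and the shift speed(s).  ``overrides`` may replace ``c2`` (fig6),
    ``z`` (fig7), or ``epsilon``.
    """
    if name in ("fig4", "fig5"):
        eps = float(overrides.get("epsilon", 0.1))
        c = float(overrides.get("c", 1.0))
        comps = (make_bump(35.0, 2.5, 4, c), make_bump(40.0, 2.5, 2, c))
        land = compose_landscape(comps, d=0.5, case_tag=CASE1, epsilon=eps)
        return {
            "name": name,
            "landscape": land,
            "c": c,
            "initial": gaussian_initial_condition(37.5, 0.1, 10.0),
            "epsilon": eps,
        }
    if name == "fig6":
        eps = float(overrides.get("epsilon", 0.1))
        c1 = float(overrides.get("c1", -1.0))
        c2 = float(overrides.get("c2", 2.5))
        comps = (make_bump(32.0, 1.75, 2, c1), make_bump(48.0, 2.5, 2, c2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # this scenario uses d = -1/2
            land = compose_landscape(comps, d=-0.5, case_tag=CASE2, epsilon=eps)
        return {
            "name": name,
            "landscape": land,
            "c_pair": (c1, c2),
            "initial": gaussian_initial_condition(37.5, 0.1, 10.0),
            "epsilon": eps,
        }
    if name == "fig7":
        eps = float(overrides.get("epsilon", 0.1))
        z = float(overrides.get("z", 4.0))
        comps = (make_bump(28.0 + z, 1.75, 2, -1.0), make_bump(52.0 - z, 2.5, 2, 2.5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            land = compose_landscape(comps, d=-0.5, case_tag=CASE2, epsilon=eps)
        return {
            "name": name,
            "landscape": land,
            "c_pair": (-1.0, 2.5),
            "initial": gaussian_initial_condition(37.5, 0.1, 10.0),
            "epsilon": eps,
        }
    if name == "fig8":
        eps = float(overrides.get("epsilon", 0.05))
        comps = (make_bump(40.0, 1.75, 2, -1.2), make_bump(40.0, 2.5, 2, 1.2))
        land = compose_landscape(comps, d=0.5, case_tag=CASE2, epsilon=eps)
        return {
            "name": name,
            "landscape": land,
            "c_pair": (-1.2, 1.2),
            "initial": gaussian_initial_condition(37.5, 0.1, 10.0),
            "epsilon": eps,
        }
    raise ParameterError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
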