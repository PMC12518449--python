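"""Experiment presets, report assembly, and the command-line interface.

Presets reproduce the published experiments at reduced scale: a single common
shift speed with a quartic/quadratic peak pair (fig4/fig5), two peaks moving
apart at different speeds (fig6/fig7), and overlapping peaks separating
(fig8).  Every run is fully deterministic.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import click
import numpy as np
import yaml

from . import diagnostics, eigen, fd_solver, hj_solver, landscapes, viscosity
from .landscapes import CASE1, CASE2, PRESET_NAMES, preset

__all__ = ["ExperimentConfig", "run_experiment", "sweep", "cli"]

log = logging.getLogger("peaklag")


@dataclass
class ExperimentConfig:
    preset: str = "fig4"
    scheme: str = "fd"            # "fd" | "hj_eps" | "hj_limit"
    length: float = 80.0
    nx: int = 1600
    horizon: float | None = None  # per-preset default when None
    epsilon: float | None = None
    c2: float | None = None       # fig6 override
    z: float | None = None        # fig7 override
    snapshot_stride: int = 100
    out_dir: str | None = None
    eigen_radius: float = 30.0
    window_scale: float = 3.0     # window half-width = window_scale*sqrt(eps)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


_DEFAULT_HORIZON = {"fig4": 150.0, "fig5": 10.0, "fig6": 80.0,
                    "fig7": 80.0, "fig8": 100.0}


def _resolve(config: ExperimentConfig) -> dict:
    if config.preset not in PRESET_NAMES:
        raise ValueError(
            f"invalid preset {config.preset!r}; available: {', '.join(PRESET_NAMES)}")
    overrides = {}
    if config.epsilon is not None:
        overrides["epsilon"] = config.epsilon
    if config.c2 is not None and config.preset == "fig6":
        overrides["c2"] = config.c2
    if config.z is not None and config.preset == "fig7":
        overrides["z"] = config.z
    ps = preset(config.preset, **overrides)
    ps["horizon"] = (config.horizon if config.horizon is not None
                     else _DEFAULT_HORIZON[config.preset])
    return ps


def _tail_check(result, lambda_eps):
    """rho-limit check with the tail fraction widened on short runs."""
    n = len(result.rho)
    tail_fraction = max(0.1, min(1.0, 110.0 / n))
    if n * tail_fraction < 100:
        return None
    return diagnostics.rho_limit_check(result.rho_times, result.rho,
                                       lambda_eps, tail_fraction=tail_fraction)


def _fd_case1_summary(config, ps, result) -> dict:
    land = ps["landscape"]
    c = ps["c"]
    eps = ps["epsilon"]
    pred = viscosity.concentration_points(land, c)
    final_cm = diagnostics.comoving(result.final, c, eps)
    window = config.window_scale * math.sqrt(eps)
    cands = [cand.location for cand in pred.candidates]
    rep = diagnostics.locate_mass(final_cm, cands, window)
    summary = {
        "case": "case1",
        "candidates": cands,
        "shallowest_prediction": [cand.location for cand in pred.shallowest],
        "final_fractions": list(rep.fractions) if rep.fractions else None,
        "dominant_candidate": (cands[rep.dominant]
                               if rep.dominant is not None else None),
        "argmax_comoving": rep.argmax_location,
        "rho_final": rep.rho,
        "extinct": rep.extinct,
    }
    if not rep.extinct:
        pair = eigen.principal_eigenpair_drift(
            land.frozen, c, eps, config.eigen_radius)
        summary["lambda_eps"] = pair.eigenvalue
        rho_rep = _tail_check(result, pair.eigenvalue)
        if rho_rep is not None:
            summary["rho_tail"] = rho_rep.rho_tail
            summary["rho_relative_gap"] = rho_rep.relative_gap
            summary["rho_tail_monotone"] = rho_rep.tail_monotone
    return summary


def _fd_case2_summary(config, ps, result) -> dict:
    land = ps["landscape"]
    c1, c2 = ps["c_pair"]
    eps = ps["epsilon"]
    comp1 = next(cc for cc in land.components if cc.shift_speed < 0)
    comp2 = next(cc for cc in land.components if cc.shift_speed > 0)
    report = eigen.persistence_classification(
        comp1, comp2, c1, c2, land.death_rate, eps, radius=10.0)
    xbar1 = landscapes.component_lagged_optimum(comp1, c1)
    xbar2 = landscapes.component_lagged_optimum(comp2, c2)
    window = config.window_scale * math.sqrt(eps)
    times, fracs = diagnostics.track_mass_series(
        result,
        [lambda t, x=xbar1: x + eps * c1 * t,
         lambda t, x=xbar2: x + eps * c2 * t],
        window)
    frac1, frac2 = fracs[:, 0], fracs[:, 1]
    final_dom = 1 if frac1[-1] > frac2[-1] else 2
    # transient overtaking: track 2 dominates during an early phase, then the
    # higher-lagged-fitness track 1 takes over by the end of the run
    k_star = int(np.argmax(frac2))
    overtaking = bool(final_dom == 1
                      and k_star < len(frac2) // 2
                      and frac2[k_star] > max(frac1[k_star], 0.5))
    rho_rep = None
    lam_min = min(report.lambda1, report.lambda2)
    if lam_min < 0:
        rho_rep = _tail_check(result, lam_min)
    return {
        "case": "case2",
        "lambda1": report.lambda1,
        "lambda2": report.lambda2,
        "verdict": report.verdict,
        "dominant_index_eigen": report.dominant_index,
        "lagged_fitnesses": list(report.lagged_fitnesses),
        "lagged_optima_tracks": [xbar1, xbar2],
        "final_track_fractions": [float(frac1[-1]), float(frac2[-1])],
        "dominant_index_simulation": final_dom,
        "transient_overtaking": overtaking,
        "rho_final": float(result.rho[-1]),
        "rho_tail_monotone": (rho_rep.tail_monotone if rho_rep else None),
        "rho_tail": (rho_rep.rho_tail if rho_rep else None),
    }


def _run_fd(config: ExperimentConfig, ps: dict) -> tuple[dict, fd_solver.SimulationResult]:
    land = ps["landscape"]
    eps = ps["epsilon"]
    grid = fd_solver.TraitGrid(config.length, config.nx)
    rho0 = float(grid.dx * np.sum(ps["initial"](grid.nodes)))
    dt_max = fd_solver.stable_dt(grid, eps, land, rho_bound=rho0 + 2.0)
    horizon = ps["horizon"]
    nt = int(math.ceil(horizon / dt_max))
    tg = fd_solver.TimeGrid(horizon, nt)
    log.info("fd run: preset=%s dt=%.4g nt=%d cfl=%.4g", config.preset,
             tg.dt, nt, dt_max)
    result = fd_solver.run(land, ps["initial"], grid, tg, eps,
                           snapshot_stride=config.snapshot_stride)
    if land.case_tag == CASE1:
        summary = _fd_case1_summary(config, ps, result)
    else:
        summary = _fd_case2_summary(config, ps, result)
    return summary, result


def _run_hj(config: ExperimentConfig, ps: dict, limit: bool) -> tuple[dict, tuple]:
    land = ps["landscape"]
    if land.case_tag != CASE1:
        raise ValueError("the HJ schemes apply to the common-speed case only")
    eps = ps["epsilon"]
    c = ps["c"]
    grid = fd_solver.TraitGrid(config.length, config.nx)
    x = grid.nodes
    u0 = -eps * (math.log(0.1) - (x - 37.5) ** 2 / 100.0)
    horizon = ps["horizon"]
    if limit:
        snaps, times, series = hj_solver.run_limit(u0 - u0.min(), land, grid,
                                                   c, horizon)
        label = "P_n"
    else:
        snaps, times, series = hj_solver.run_eps(u0, land, grid, eps, c, horizon)
        label = "rho_n"
    final = snaps[-1]
    argmin_x = float(x[np.argmin(final.phase)])
    pred = viscosity.concentration_points(land, c)
    target = pred.shallowest[0].location if pred.shallowest else None
    summary = {
        "scheme": "hj_limit" if limit else "hj_eps",
        "argmin_final": argmin_x,
        "predicted_lagged_optimum": target,
        "argmin_error": (abs(argmin_x - target) if target is not None else None),
        f"final_{label}": float(series[-1]),
    }
    return summary, (snaps, times, series)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one configured experiment and return (and optionally write) a summary."""
    ps = _resolve(config)
    land = ps["landscape"]
    c_or_pair = ps.get("c", ps.get("c_pair"))
    assumptions = landscapes.validate_assumptions(land, c_or_pair)
    artifacts = {}
    if config.scheme == "fd":
        summary, result = _run_fd(config, ps)
        artifacts["mass_table"] = result.mass_table()
        artifacts["snapshots"] = result
    elif config.scheme in ("hj_eps", "hj_limit"):
        summary, (snaps, times, series) = _run_hj(
            config, ps, limit=(config.scheme == "hj_limit"))
        artifacts["mass_table"] = np.column_stack([times, series])
        artifacts["snapshots"] = snaps
    else:
        raise ValueError(f"unknown scheme {config.scheme!r}")
    summary["preset"] = config.preset
    summary["scheme"] = config.scheme
    summary["epsilon"] = ps["epsilon"]
    summary["horizon"] = ps["horizon"]
    summary["assumptions_ok"] = assumptions.all_passed
    if config.out_dir:
        _write_outputs(config, summary, artifacts)
    return summary


def _write_outputs(config: ExperimentConfig, summary: dict, artifacts: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / f"{config.preset}_{config.scheme}_mass.csv",
               artifacts["mass_table"], delimiter=",", header="time,value",
               comments="")
    snaps = artifacts["snapshots"]
    if isinstance(snaps, fd_solver.SimulationResult):
        cols = [snaps.grid.nodes] + [s.density for s in snaps.snapshots]
        headers = ["x"] + [f"t={s.time:.6g}" for s in snaps.snapshots]
    else:
        cols = [snaps[0].grid.nodes] + [s.phase for s in snaps]
        headers = ["x"] + [f"t={s.time:.6g}" for s in snaps]
    np.savetxt(out / f"{config.preset}_{config.scheme}_snapshots.csv",
               np.column_stack(cols), delimiter=",",
               header=",".join(headers), comments="")
    with open(out / f"{config.preset}_{config.scheme}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


def sweep(config: ExperimentConfig, parameter: str,
          values: Sequence[float]) -> dict:
    """Re-run an experiment over parameter values; brackets dominance switches."""
    if parameter not in ("c2", "epsilon", "d", "z"):
        raise ValueError(f"unsupported sweep parameter {parameter!r}")
    rows = []
    for v in values:
        cfg = ExperimentConfig(**{**asdict(config), "out_dir": None})
        if parameter == "c2":
            cfg.c2 = float(v)
        elif parameter == "epsilon":
            cfg.epsilon = float(v)
        elif parameter == "z":
            cfg.z = float(v)
        else:
            raise NotImplementedError("d sweep requires a custom landscape")
        summary = run_experiment(cfg)
        summary[parameter] = float(v)
        rows.append(summary)
    bracket = None
    key = ("dominant_index_eigen" if rows and "dominant_index_eigen" in rows[0]
           else "dominant_candidate")
    for r1, r2 in zip(rows, rows[1:]):
        if r1.get(key) != r2.get(key):
            bracket = (r1[parameter], r2[parameter])
    return {"rows": rows, "switch_bracket": bracket, "parameter": parameter}


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def cli():
    """Shifting-optimum population dynamics workbench."""
    logging.basicConfig(level=logging.INFO, format="%(message)s")


def _common_config(preset_name, config_path, epsilon, c2, scheme, out):
    if config_path:
        cfg = ExperimentConfig.from_yaml(config_path)
    else:
        cfg = ExperimentConfig()
    if preset_name:
        cfg.preset = preset_name
    if epsilon is not None:
        cfg.epsilon = epsilon
    if c2 is not None:
        cfg.c2 = c2
    if scheme:
        cfg.scheme = scheme
    if out:
        cfg.out_dir = out
    return cfg


@cli.command()
@click.option("--preset", "preset_name", type=str, default=None)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--epsilon", type=float, default=None)
@click.option("--c2", type=float, default=None)
@click.option("--scheme", type=click.Choice(["fd", "hj_eps", "hj_limit"]),
              default="fd")
@click.option("--out", type=click.Path(), default=None)
def simulate(preset_name, config_path, epsilon, c2, scheme, out):
    """Run a preset simulation and print its summary."""
    cfg = _common_config(preset_name, config_path, epsilon, c2, scheme, out)
    summary = run_experiment(cfg)
    click.echo(json.dumps(summary, indent=2, default=float))


@cli.command("hj")
@click.option("--preset", "preset_name", type=str, default="fig5")
@click.option("--epsilon", type=float, default=None)
@click.option("--scheme", type=click.Choice(["hj_eps", "hj_limit"]),
              default="hj_eps")
@click.option("--out", type=click.Path(), default=None)
def hj_cmd(preset_name, epsilon, scheme, out):
    """Run a Hamilton-Jacobi scheme on a common-speed preset."""
    cfg = _common_config(preset_name, None, epsilon, None, scheme, out)
    summary = run_experiment(cfg)
    click.echo(json.dumps(summary, indent=2, default=float))


@cli.command("eigen")
@click.option("--preset", "preset_name", type=str, default="fig4")
@click.option("--epsilon", type=float, default=None)
@click.option("--c", type=float, default=None)
@click.option("--radius", type=float, default=30.0)
def eigen_cmd(preset_name, epsilon, c, radius):
    """Principal eigenvalue of a preset landscape."""
    overrides = {}
    if epsilon is not None:
        overrides["epsilon"] = epsilon
    ps = preset(preset_name, **overrides)
    land = ps["landscape"]
    cc = c if c is not None else ps.get("c", 0.0)
    pair = eigen.principal_eigenpair_drift(land.frozen, cc, ps["epsilon"], radius)
    click.echo(json.dumps({"lambda": pair.eigenvalue, "epsilon": ps["epsilon"],
                           "c": cc, "radius": radius}, indent=2))


@cli.command("lagged")
@click.option("--preset", "preset_name", type=str, default="fig4")
@click.option("--c", type=float, default=None)
def lagged_cmd(preset_name, c):
    """Lagged-optimum prediction table for a preset landscape."""
    ps = preset(preset_name)
    land = ps["landscape"]
    cc = c if c is not None else ps.get("c", 1.0)
    pred = viscosity.concentration_points(land, cc)
    click.echo(json.dumps(pred.table(), indent=2))


@cli.command("sweep")
@click.option("--preset", "preset_name", type=str, default="fig6")
@click.option("--parameter", type=click.Choice(["c2", "epsilon", "z"]),
              default="c2")
@click.option("--values", type=str, required=True,
              help="comma-separated values, e.g. '1,1.5,2,2.5'")
@click.option("--out", type=click.Path(), default=None)
def sweep_cmd(preset_name, parameter, values, out):
    """Sweep one parameter over a preset and report dominance switching."""
    cfg = ExperimentConfig(preset=preset_name)
    vals = [float(v) for v in values.split(",") if v.strip()]
    res = sweep(cfg, parameter, vals)
    text = json.dumps(res, indent=2, default=float)
    if out:
        Path(out).parent.mkdir(parents=True, exist_ok=True)
        Path(out).write_text(text)
    click.echo(text)


@cli.command("report")
@click.option("--preset", "preset_name", type=str, default="fig4")
@click.option("--out", type=click.Path(), required=True)
def report_cmd(preset_name, out):
    """Full theory-vs-simulation report for one preset."""
    cfg = ExperimentConfig(preset=preset_name, out_dir=out)
    summary = run_experiment(cfg)
    click.echo(json.dumps(summary, indent=2, default=float))
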