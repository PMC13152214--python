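"""Scaling pipeline: both tasks, both control strategies, ten body sizes.

For each body mass on the 1 g – 10 t grid the pipeline materializes the
task parameters from the allometric input laws, optimizes the delayed-PD
feedback gains (fastest zero-overshoot response) and the bang-bang switch
time (minimum-time benchmark), and fits power laws to the optimized
outputs against body mass.  Response-time laws are reported with
coefficients in milliseconds at 1 kg.

The pipeline also evaluates the time available for a correction: the swing
duration at maximum sprint speed (an input law) for the swing task, and
the time to fall one leg length under gravity, ``sqrt(2 L / g)``, for the
posture task.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allometry import (
    GRAVITY,
    PowerLawFit,
    animal_parameters,
    evaluate_law,
    fit_power_law,
    parameter_laws,
    size_grid,
)
from .dynamics import TaskConfig
from .optimizers import OptimizationResult, optimize_gains, optimize_switch_time

__all__ = [
    "ScalingRun",
    "run_task_scaling",
    "available_time",
    "compare_strategies",
    "report",
]

#: Output columns fitted with a power law, with the scale factor applied
#: before fitting (times are fitted in ms to match the tabulated form).
_FIT_COLUMNS = {
    "kp": ("kp", 1.0),
    "kd": ("kd", 1.0),
    "feedback_response_ms": ("fb_response", 1e3),
    "t_switch_ms": ("t_switch", 1e3),
    "feedforward_response_ms": ("ff_response", 1e3),
}


@dataclass
class ScalingRun:
    """Per-size optimization results and the power-law fits across sizes."""

    task: str
    records: pd.DataFrame
    fits: dict[str, PowerLawFit]
    seed: int
    partial: bool = False  # True if any size was infeasible
    results: list[tuple[OptimizationResult, OptimizationResult]] = field(default_factory=list)


def available_time(task: str, mass: float) -> float:
    """Shortest time available for a corrective response, in seconds.

    Swing: the swing duration at maximum sprint speed (tabulated law).
    Posture: the time to fall freely through one leg length,
    ``sqrt(2 L / g)`` with the leg-length law — itself a power law in mass.
    """
    if task == "swing":
        return evaluate_law(parameter_laws()["swing"]["available_time"], mass) * 1e-3
    if task == "posture":
        leg = evaluate_law(parameter_laws()["posture"]["l_com"], mass)
        return math.sqrt(2.0 * leg / GRAVITY)
    raise ValueError(f"unknown task {task!r}")


def run_task_scaling(
    task: str,
    masses=None,
    movement_deg: float = 30.0,
    froude: float = 0.21,
    seed: int = 0,
    settling_fraction: float | None = None,
) -> ScalingRun:
    """Optimize both controllers at each mass and fit the output power laws.

    ``movement_deg`` sets the swing repositioning size (default the 30-deg
    trip response, -15 to +15 deg); ``froude`` the posture perturbation.
    ``settling_fraction`` overrides the 2% settling band half-width (as a
    fraction) for sensitivity analyses.  Sizes where an optimization fails
    are excluded from the fits and flag the run as partial.
    """
    masses = list(masses) if masses is not None else size_grid()
    rows, results = [], []
    partial = False
    warm: tuple[float, float] | None = None  # previous optimum, normalized units
    for mass in masses:
        params = animal_parameters(task, mass)
        if task == "swing":
            cfg = TaskConfig.swing(-movement_deg / 2.0, movement_deg / 2.0)
        else:
            cfg = TaskConfig.posture(params, froude)
        extra = None
        if warm is not None:
            # optimal gains vary smoothly with size in normalized units;
            # seed each size with the neighbor's optimum rescaled by
            # I/t_sm^2 and I/t_sm
            extra = [
                (
                    warm[0] * params.inertia / params.t_sm**2,
                    warm[1] * params.inertia / params.t_sm,
                )
            ]
        fb = optimize_gains(
            params, cfg, seed=seed, extra_starts=extra, settling_fraction=settling_fraction
        )
        if fb.converged:
            warm = (
                fb.best_params.kp * params.t_sm**2 / params.inertia,
                fb.best_params.kd * params.t_sm / params.inertia,
            )
        ff = optimize_switch_time(params, cfg, seed=seed)
        results.append((fb, ff))
        ok = fb.converged and ff.converged
        partial = partial or not ok
        rows.append(
            dict(
                mass=mass,
                t_sm=params.t_sm,
                kp=fb.best_params.kp if fb.converged else np.nan,
                kd=fb.best_params.kd if fb.converged else np.nan,
                tau_steadystate=fb.best_params.tau_steadystate,
                fb_response=fb.metrics.response_time if fb.converged else np.nan,
                fb_overshoot=fb.metrics.overshoot if fb.converged else np.nan,
                torque_fraction=fb.metrics.torque_fraction if fb.converged else np.nan,
                t_switch=ff.best_params.t_switch if ff.converged else np.nan,
                ff_response=ff.metrics.response_time if ff.converged else np.nan,
                available_time=available_time(task, mass),
                fb_converged=fb.converged,
                ff_converged=ff.converged,
            )
        )
    records = pd.DataFrame(rows)
    fits: dict[str, PowerLawFit] = {}
    for name, (col, scale) in _FIT_COLUMNS.items():
        vals = records[col].to_numpy() * scale
        good = np.isfinite(vals)
        if good.sum() >= 2:
            fits[name] = fit_power_law(records["mass"].to_numpy()[good], vals[good])
    return ScalingRun(
        task=task, records=records, fits=fits, seed=seed, partial=partial, results=results
    )


def compare_strategies(run: ScalingRun) -> pd.DataFrame:
    """Per-size comparison of feedback vs feedforward control.

    Columns: feedback/feedforward response-time ratio, feedback time as a
    multiple of the sensorimotor delay, both response times as fractions
    of the available movement time, and the feedback torque fraction.
    """
    r = run.records
    if len(r) == 0:
        raise ValueError("empty scaling run")
    return pd.DataFrame(
        dict(
            mass=r["mass"],
            fb_ff_ratio=r["fb_response"] / r["ff_response"],
            fb_delay_multiple=r["fb_response"] / r["t_sm"],
            fb_available_fraction=r["fb_response"] / r["available_time"],
            ff_available_fraction=r["ff_response"] / r["available_time"],
            torque_fraction=r["torque_fraction"],
        )
    )


def report(run: ScalingRun, comparison: pd.DataFrame | None, outdir: str | Path) -> dict[str, Path]:
    """Write fitted-law, per-size and comparison tables plus a JSON summary.

    The fitted-law CSV mirrors the tabulated (parameter, source,
    coefficient, exponent) layout, combining the input laws with the
    fitted output laws; r-squared values of the fits are included.
    """
    if len(run.records) == 0:
        raise ValueError("empty scaling run")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if comparison is None:
        comparison = compare_strategies(run)

    law_rows = [
        dict(
            parameter=name,
            source="literature",
            coefficient=law.coefficient,
            exponent=law.exponent,
            r_squared=np.nan,
        )
        for name, law in parameter_laws()[run.task].items()
    ]
    law_rows += [
        dict(
            parameter=name,
            source="optimization",
            coefficient=fit.coefficient,
            exponent=fit.exponent,
            r_squared=fit.r_squared,
        )
        for name, fit in run.fits.items()
    ]
    paths = {
        "laws": outdir / f"{run.task}_laws.csv",
        "records": outdir / f"{run.task}_per_size.csv",
        "comparison": outdir / f"{run.task}_comparison.csv",
        "summary": outdir / f"{run.task}_summary.json",
    }
    pd.DataFrame(law_rows).to_csv(paths["laws"], index=False)
    run.records.to_csv(paths["records"], index=False)
    comparison.to_csv(paths["comparison"], index=False)
    summary = dict(
        task=run.task,
        seed=run.seed,
        partial=run.partial,
        masses=list(run.records["mass"]),
        fits={
            name: dict(coefficient=f.coefficient, exponent=f.exponent, r_squared=f.r_squared)
            for name, f in run.fits.items()
        },
    )
    paths["summary"].write_text(json.dumps(summary, indent=2))
    return paths
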