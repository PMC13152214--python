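"""The dimensionless single-free-parameter feedback system.

Dividing the delayed-PD torque balance of the gravity-free double
integrator by ``I * theta_r / t_sm**2`` yields a normalized system with
unit inertia, unit delay and unit reference; the normalized force capacity
``tau_iso_bar = tau_iso * t_sm**2 / (I * theta_r)`` is its only free
parameter.  Normalized gains relate to dimensional ones by
``kp_bar = kp * t_sm**2 / I`` and ``kd_bar = kd * t_sm / I``, and the
normalized response time is ``t_resp / t_sm``.

Sweeping ``tau_iso_bar`` and re-optimizing the gains at each point maps the
delay-limited / force-limited transition: a high region where the optimum
never touches the force limit (response time constant at the unconstrained
optimum), a middle region where only the positive (acceleration-phase)
torque is clipped, and a low region where the braking torque saturates too
and response times grow steeply.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .allometry import AnimalParams
from .dynamics import FeedbackGains, TaskConfig
from .engine import Trajectory, simulate_feedback
from .optimizers import OptimizationResult, optimize_gains

__all__ = [
    "NormalizedConfig",
    "SweepResult",
    "unit_plant",
    "normalized_task",
    "simulate_normalized",
    "optimize_normalized_gains",
    "sweep_force_capacity",
    "classify_regions",
    "write_sweep_csv",
    "SATURATION_RTOL",
]

#: A peak torque within this relative margin of the capacity limit counts
#: as saturated.
SATURATION_RTOL = 1e-6


@dataclass(frozen=True)
class NormalizedConfig:
    """Configuration of the normalized feedback system.

    ``tau_iso_bar`` may be ``inf`` (no force limit).  The posture variant
    (unit perturbation velocity, zero reference) mirrors the swing one but
    its normalization constant is not pinned by the dimensional model; it
    is provided as an experimental convenience.
    """

    tau_iso_bar: float = math.inf
    task_variant: str = "swing"
    gains_bar: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.tau_iso_bar > 0:
            raise ValueError("tau_iso_bar must be positive")
        if self.task_variant not in ("swing", "posture"):
            raise ValueError(f"unknown task variant {self.task_variant!r}")


def unit_plant(tau_iso_bar: float = math.inf, task_variant: str = "swing") -> AnimalParams:
    """Unit-inertia, unit-delay, gravity-free plant of the normalized system."""
    return AnimalParams(
        task=task_variant,
        body_mass=1.0,
        t_sm=1.0,
        inertia=1.0,
        l_com=1.0,
        tau_iso=tau_iso_bar,
        limb_mass=0.0 if task_variant == "swing" else None,
        g=0.0,
    )


def normalized_task(task_variant: str = "swing") -> TaskConfig:
    """Initial/target states of the normalized task.

    Swing: step from rest at 0 to rest at the unit reference.  Posture:
    unit velocity perturbation at the reference, return to rest.
    """
    if task_variant == "swing":
        return TaskConfig(task="swing", theta0=0.0, omega0=0.0, theta_ref=1.0, movement_size=1.0)
    return TaskConfig(task="posture", theta0=0.0, omega0=1.0, theta_ref=0.0, movement_size=1.0)


def simulate_normalized(cfg: NormalizedConfig) -> Trajectory:
    """Simulate the normalized system at the gains stored in ``cfg``."""
    if cfg.gains_bar is None:
        raise ValueError("cfg.gains_bar must be set to simulate")
    params = unit_plant(cfg.tau_iso_bar, cfg.task_variant)
    task = normalized_task(cfg.task_variant)
    return simulate_feedback(params, FeedbackGains(*cfg.gains_bar), task)


def optimize_normalized_gains(
    tau_iso_bar: float = math.inf,
    task_variant: str = "swing",
    seed: int = 0,
    starts: list[tuple[float, float]] | None = None,
) -> OptimizationResult:
    """Fastest zero-overshoot gains of the normalized system."""
    params = unit_plant(tau_iso_bar, task_variant)
    return optimize_gains(params, normalized_task(task_variant), seed=seed, starts=starts)


@dataclass
class SweepResult:
    """Per-point optima of a force-capacity sweep (ascending tau_iso_bar)."""

    table: pd.DataFrame
    task_variant: str = "swing"

    @property
    def grid(self) -> np.ndarray:
        return self.table["tau_iso_bar"].to_numpy()


def sweep_force_capacity(
    grid,
    task_variant: str = "swing",
    seed: int = 0,
) -> SweepResult:
    """Optimize gains for each force capacity in ``grid`` (ascending).

    Points are processed from high to low capacity, warm-starting each
    optimization from the neighbor's optimum (the middle/low regions have
    many near-equal local minima; warm starts stabilize the curve).  The
    unconstrained optimum seeds the first (largest) point.  Infeasible
    points are recorded with NaN outputs and the sweep continues.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive and strictly ascending")
    task = normalized_task(task_variant)

    rows = []
    warm: list[tuple[float, float]] | None = None
    for tau_bar in grid[::-1]:
        params = unit_plant(tau_bar, task_variant)
        # warm-started points run a single local descent; the first
        # (largest-capacity) point gets the full multi-start search
        res = optimize_gains(params, task, seed=seed, starts=warm, thorough=warm is None)
        if res.converged and res.metrics is not None:
            m = res.metrics
            kp, kd = res.best_params.kp, res.best_params.kd
            sat_pos = m.peak_tau_pos >= (1.0 - SATURATION_RTOL) * tau_bar
            sat_neg = -m.peak_tau_neg >= (1.0 - SATURATION_RTOL) * tau_bar
            rows.append(
                dict(
                    tau_iso_bar=tau_bar,
                    kp_bar=kp,
                    kd_bar=kd,
                    t_resp_bar=m.response_time,
                    peak_pos=m.peak_tau_pos,
                    peak_neg=m.peak_tau_neg,
                    saturated_pos=sat_pos,
                    saturated_neg=sat_neg,
                    feasible=True,
                )
            )
            warm = [(kp, kd), (kp * 0.9, kd), (kp, kd * 0.9), (kp * 1.1, kd * 1.1)]
        else:
            rows.append(
                dict(
                    tau_iso_bar=tau_bar,
                    kp_bar=np.nan,
                    kd_bar=np.nan,
                    t_resp_bar=np.nan,
                    peak_pos=np.nan,
                    peak_neg=np.nan,
                    saturated_pos=False,
                    saturated_neg=False,
                    feasible=False,
                )
            )
            warm = None  # fall back to the default start grid

    table = pd.DataFrame(rows[::-1]).reset_index(drop=True)
    table["region"] = np.where(
        ~table["feasible"],
        "infeasible",
        np.where(
            ~table["saturated_pos"],
            "high",
            np.where(~table["saturated_neg"], "middle", "low"),
        ),
    )
    return SweepResult(table=table, task_variant=task_variant)


def classify_regions(sweep: SweepResult) -> tuple[float, float, float]:
    """Region boundaries of a sweep: (high boundary, middle boundary, low floor).

    high boundary — largest capacity at which the positive torque
    saturates (delay-limited above it); middle boundary — largest capacity
    at which the braking torque saturates as well; low floor — smallest
    capacity with a feasible zero-overshoot settle.  NaN where a boundary
    is absent from the sweep.
    """
    tb = sweep.table
    feas = tb[tb["feasible"]]
    pos = feas[feas["saturated_pos"]]
    neg = feas[feas["saturated_neg"]]
    high = float(pos["tau_iso_bar"].max()) if len(pos) else math.nan
    mid = float(neg["tau_iso_bar"].max()) if len(neg) else math.nan
    low = float(feas["tau_iso_bar"].min()) if len(feas) else math.nan

    sat = feas["saturated_pos"].to_numpy()
    if sat.any():
        k = int(np.flatnonzero(sat)[-1])
        if sat[: k + 1].sum() != k + 1:
            warnings.warn("non-monotone saturation pattern across the sweep")
    return high, mid, low


def write_sweep_csv(sweep: SweepResult, path: str | Path) -> Path:
    """Write the sweep table as CSV."""
    path = Path(path)
    sweep.table.to_csv(path, index=False)
    return path


def plot_sweep(sweep: SweepResult, path: str | Path) -> Path:
    """Response time and gains vs force capacity, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tb = sweep.table[sweep.table["feasible"]]
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    ax1.plot(tb["tau_iso_bar"], tb["t_resp_bar"], "k-")
    ax1.set_ylabel("normalized response time")
    ax2.plot(tb["tau_iso_bar"], tb["kp_bar"], label="kp_bar")
    ax2.plot(tb["tau_iso_bar"], tb["kd_bar"], label="kd_bar")
    ax2.set_xlabel("normalized force capacity")
    ax2.set_ylabel("optimal gains")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
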