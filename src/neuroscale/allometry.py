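"""Allometric parameter laws and power-law regression.

Every physical and neural parameter of the pendulum models is described by
an allometric power law, ``parameter = a * M**b``, where ``M`` is body mass
in kg, ``a`` is the parameter's value for a 1 kg animal (in the parameter's
natural units) and ``b`` is a dimensionless exponent.  The laws for the two
tasks (swing-limb repositioning and posture recovery) are shipped as a CSV
table in :mod:`neuroscale.data` and can be overridden from a user-supplied
CSV or YAML file.

The same power-law form is fitted to pipeline outputs (controller gains,
response times) by ordinary least squares on log10-transformed data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AllometricLaw",
    "AnimalParams",
    "PowerLawFit",
    "GRAVITY",
    "SIZE_GRID_KG",
    "load_parameter_laws",
    "parameter_laws",
    "evaluate_law",
    "animal_parameters",
    "size_grid",
    "fit_power_law",
    "materialize_grid",
    "write_parameter_grid",
]

#: Gravitational acceleration used throughout, m/s^2.
GRAVITY = 9.81

#: Ten body masses in kg: eight log-spaced decades from 1 g to 10 t,
#: plus 5 g and 5 t.
SIZE_GRID_KG = (1e-3, 5e-3, 1e-2, 1e-1, 1.0, 10.0, 1e2, 1e3, 5e3, 1e4)

@dataclass(frozen=True)
class AllometricLaw:
    """A power law ``value(M) = coefficient * M**exponent``.

    Parameters
    ----------
    coefficient
        Value of the parameter at M = 1 kg, in `units`.  Must be > 0.
    exponent
        Dimensionless scaling exponent.
    units
        Unit label, e.g. ``"ms"`` or ``"N.m"``.
    """

    coefficient: float
    exponent: float
    units: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficient) or self.coefficient <= 0:
            raise ValueError(f"coefficient must be positive, got {self.coefficient}")
        if not np.isfinite(self.exponent):
            raise ValueError(f"exponent must be finite, got {self.exponent}")

    def __call__(self, mass: float) -> float:
        return evaluate_law(self, mass)


@dataclass(frozen=True)
class AnimalParams:
    """Fully materialized physical parameters for one task at one body mass.

    All quantities are strict SI (s, kg, m, N.m).  ``limb_mass`` is only
    meaningful for the swing task (the posture plant is a point mass equal
    to the whole body mass).  ``g`` may be set to 0 to obtain the
    gravity-free double-integrator plant used by the normalized model.
    """

    task: str
    body_mass: float  # kg
    t_sm: float  # sensorimotor delay, s
    inertia: float  # kg.m^2, about the controlled joint / ground contact
    l_com: float  # m; swing: shoulder-to-COM distance, posture: leg length
    tau_iso: float  # N.m, maximum isometric torque (may be +inf)
    limb_mass: float | None = None  # kg, swing only
    g: float = GRAVITY  # m/s^2

    def __post_init__(self) -> None:
        if self.task not in ("swing", "posture"):
            raise ValueError(f"unknown task {self.task!r}")
        for name in ("body_mass", "t_sm", "inertia", "l_com", "tau_iso"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.task == "swing":
            if self.limb_mass is None or self.limb_mass < 0:
                raise ValueError("swing task requires limb_mass >= 0")
        if self.g < 0:
            raise ValueError("g must be >= 0")


@dataclass(frozen=True)
class PowerLawFit:
    """Result of an OLS power-law fit on log10-transformed data."""

    coefficient: float
    exponent: float
    r_squared: float

    def __call__(self, mass: float | np.ndarray) -> float | np.ndarray:
        return self.coefficient * np.asarray(mass, dtype=float) ** self.exponent


# ---------------------------------------------------------------------------
# Parameter-law table
# ---------------------------------------------------------------------------

def load_parameter_laws(path: str | Path | None = None) -> dict[str, dict[str, AllometricLaw]]:
    """Load the allometric law table, keyed as ``laws[task][parameter]``.

    With no argument, loads the packaged table (sensorimotor delay, segment
    inertia/mass/length and maximum isometric torque laws for both tasks).
    A user CSV with the same columns (task, parameter, coefficient,
    exponent, units) or a YAML mapping ``{task: {parameter: {coefficient,
    exponent, units}}}`` overrides it row by row.
    """
    if path is None:
        with resources.files("neuroscale.data").joinpath("parameter_laws.csv").open() as fh:
            table = pd.read_csv(fh)
        return _laws_from_frame(table)

    path = Path(path)
    base = load_parameter_laws(None)
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml

        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        for task, params in override.items():
            for name, entry in params.items():
                base.setdefault(task, {})[name] = AllometricLaw(
                    coefficient=float(entry["coefficient"]),
                    exponent=float(entry["exponent"]),
                    units=str(entry.get("units", "")),
                )
        return base
    table = pd.read_csv(path)
    for task, laws in _laws_from_frame(table).items():
        base.setdefault(task, {}).update(laws)
    return base


def _laws_from_frame(table: pd.DataFrame) -> dict[str, dict[str, AllometricLaw]]:
    laws: dict[str, dict[str, AllometricLaw]] = {}
    for row in table.itertuples(index=False):
        laws.setdefault(row.task, {})[row.parameter] = AllometricLaw(
            coefficient=float(row.coefficient),
            exponent=float(row.exponent),
            units=str(row.units),
        )
    return laws


_DEFAULT_LAWS: dict[str, dict[str, AllometricLaw]] | None = None


def parameter_laws() -> dict[str, dict[str, AllometricLaw]]:
    """The packaged default law table (cached)."""
    global _DEFAULT_LAWS
    if _DEFAULT_LAWS is None:
        _DEFAULT_LAWS = load_parameter_laws(None)
    return _DEFAULT_LAWS


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def evaluate_law(law: AllometricLaw, mass: float) -> float:
    """Evaluate ``law.coefficient * mass**law.exponent`` at ``mass`` (kg)."""
    if not mass > 0:
        raise ValueError(f"mass must be strictly positive, got {mass}")
    return law.coefficient * mass ** law.exponent


def animal_parameters(
    task: str,
    mass: float,
    laws: Mapping[str, Mapping[str, AllometricLaw]] | None = None,
) -> AnimalParams:
    """Materialize :class:`AnimalParams` for one task at one body mass.

    Time-valued laws (tabulated in ms) are converted to seconds.  For the
    posture task the maximum isometric torque law already aggregates the
    plantarflexors of all four legs; it is used as tabulated.
    """
    if task not in ("swing", "posture"):
        raise ValueError(f"unknown task {task!r}")
    if not mass > 0:
        raise ValueError(f"mass must be strictly positive, got {mass}")
    task_laws = (laws or parameter_laws())[task]
    t_sm = evaluate_law(task_laws["t_sm"], mass) * 1e-3  # ms -> s
    common = dict(
        task=task,
        body_mass=mass,
        t_sm=t_sm,
        inertia=evaluate_law(task_laws["inertia"], mass),
        l_com=evaluate_law(task_laws["l_com"], mass),
        tau_iso=evaluate_law(task_laws["tau_iso"], mass),
    )
    if task == "swing":
        return AnimalParams(limb_mass=evaluate_law(task_laws["limb_mass"], mass), **common)
    return AnimalParams(**common)


def size_grid() -> list[float]:
    """The 10-animal body-mass grid in kg, ascending (1 g to 10 t)."""
    return list(SIZE_GRID_KG)


def fit_power_law(masses: Iterable[float], values: Iterable[float]) -> PowerLawFit:
    """OLS fit of ``values = a * masses**b`` on log10-transformed data.

    r_squared is the coefficient of determination of the linear fit on the
    log scale.  Requires at least two points and strictly positive data.
    """
    m = np.asarray(list(masses), dtype=float)
    v = np.asarray(list(values), dtype=float)
    if m.size != v.size:
        raise ValueError("masses and values must have the same length")
    if m.size < 2:
        raise ValueError("power-law fit requires at least two points")
    if np.any(m <= 0) or np.any(v <= 0) or not (np.all(np.isfinite(m)) and np.all(np.isfinite(v))):
        raise ValueError("power-law fit requires strictly positive finite data")
    x, y = np.log10(m), np.log10(v)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(coefficient=float(10.0**intercept), exponent=float(slope), r_squared=r2)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def materialize_grid(task: str, masses: Iterable[float] | None = None) -> pd.DataFrame:
    """Materialize parameters for each mass as a tidy DataFrame (SI units)."""
    rows = []
    for mass in masses if masses is not None else size_grid():
        p = animal_parameters(task, mass)
        rows.append(
            dict(
                task=p.task,
                body_mass=p.body_mass,
                t_sm=p.t_sm,
                inertia=p.inertia,
                l_com=p.l_com,
                tau_iso=p.tau_iso,
                limb_mass=p.limb_mass,
                g=p.g,
            )
        )
    return pd.DataFrame(rows)


def write_parameter_grid(task: str, path: str | Path, masses: Iterable[float] | None = None) -> Path:
    """Write the materialized parameter grid as CSV or JSON (by extension)."""
    path = Path(path)
    frame = materialize_grid(task, masses)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    else:
        frame.to_csv(path, index=False)
    return path
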