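"""Plant torques and control laws for the swing and posture pendulums.

Two single-degree-of-freedom plants share the torque balance
``I * theta_ddot = tau_act + tau_gravity``:

* swing task — a distributed-mass pendulum forelimb hanging from the
  shoulder; angle zero is vertically down, counter-clockwise positive, so
  gravity is restoring: ``tau_gravity = -M_limb * g * L_com * sin(theta)``.
* posture task — an inverted point-mass pendulum (whole body mass on a
  leg-length lever); angle zero is vertically up, counter-clockwise
  positive, so gravity is destabilizing: ``tau_gravity = M * g * L *
  sin(theta)``.

Two controllers produce the applied torque, both preceded by a pure
deadtime equal to the sensorimotor delay ``t_sm`` during which no torque is
applied: a proportional-derivative law acting on state delayed by ``t_sm``
(plus a constant steady-state torque countering gravity at the target), and
a minimum-time bang-bang law switching between the maximum isometric
torques at a single switch time.  The applied torque is always clamped to
``[-tau_iso, +tau_iso]``.

Angles are radians throughout; degrees appear only at the CLI boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .allometry import AnimalParams

__all__ = [
    "TaskConfig",
    "FeedbackGains",
    "FeedforwardPlan",
    "gravity_torque",
    "saturate",
    "pd_torque",
    "bang_bang_torque",
    "acceleration",
    "steady_state_torque",
    "froude_velocity",
]

DEG = math.pi / 180.0


@dataclass(frozen=True)
class TaskConfig:
    """Initial state, reference target and conventions for one task.

    ``movement_size`` is the angular travel ``|theta_ref - theta0|`` for the
    swing task and the dimensionless (Froude-scaled) perturbation velocity
    for the posture task.
    """

    task: str
    theta0: float  # rad
    omega0: float  # rad/s
    theta_ref: float  # rad
    movement_size: float

    @staticmethod
    def swing(theta0_deg: float = -15.0, theta_ref_deg: float = 15.0) -> "TaskConfig":
        """Swing repositioning; defaults to the -15 deg -> +15 deg trip response."""
        theta0, theta_ref = theta0_deg * DEG, theta_ref_deg * DEG
        return TaskConfig(
            task="swing",
            theta0=theta0,
            omega0=0.0,
            theta_ref=theta_ref,
            movement_size=abs(theta_ref - theta0),
        )

    @staticmethod
    def posture(
        params: AnimalParams,
        froude: float = 0.21,
        convention: str = "linear",
    ) -> "TaskConfig":
        """Posture recovery after an impulsive push of dimensionless velocity.

        The push changes the initial velocity but not the position; the
        target is rest at vertical.  ``convention`` selects the reading of
        the dimensionless velocity: ``"linear"`` (default) takes the COM
        linear speed as ``v = froude * sqrt(g*L)``; ``"squared"`` takes
        ``v = sqrt(froude * g * L)`` (Froude number as v^2/(g*L)).
        """
        return TaskConfig(
            task="posture",
            theta0=0.0,
            omega0=froude_velocity(params, froude, convention),
            theta_ref=0.0,
            movement_size=froude,
        )


def froude_velocity(params: AnimalParams, froude: float, convention: str = "linear") -> float:
    """Initial angular velocity (rad/s) of a Froude-scaled push."""
    if convention == "linear":
        v = froude * math.sqrt(params.g * params.l_com)
    elif convention == "squared":
        v = math.sqrt(froude * params.g * params.l_com)
    else:
        raise ValueError(f"unknown Froude convention {convention!r}")
    return v / params.l_com


@dataclass(frozen=True)
class FeedbackGains:
    """PD gains and the constant steady-state torque of the feedback law."""

    kp: float  # N.m/rad
    kd: float  # N.m/(rad/s)
    tau_steadystate: float = 0.0  # N.m

    def __post_init__(self) -> None:
        if self.kp < 0 or self.kd < 0:
            raise ValueError("feedback gains must be non-negative")


@dataclass(frozen=True)
class FeedforwardPlan:
    """Bang-bang plan: first torque phase sign and the single switch time."""

    t_switch: float  # s
    direction: int = 1  # sign of the first torque phase

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if not self.t_switch > 0:
            raise ValueError("t_switch must be positive")


# ---------------------------------------------------------------------------
# Torques
# ---------------------------------------------------------------------------

def gravity_torque(task: str, params: AnimalParams, theta: float) -> float:
    """Gravitational torque at angle ``theta`` (rad).

    Restoring for the hanging swing limb, destabilizing for the inverted
    posture pendulum.
    """
    if task == "swing":
        return -params.limb_mass * params.g * params.l_com * math.sin(theta)
    if task == "posture":
        return params.body_mass * params.g * params.l_com * math.sin(theta)
    raise ValueError(f"unknown task {task!r}")


def saturate(tau_des: float, tau_iso: float) -> float:
    """Clamp a desired torque to the force-capacity limits [-tau_iso, +tau_iso]."""
    if not tau_iso > 0:
        raise ValueError("tau_iso must be strictly positive")
    if tau_des > tau_iso:
        return tau_iso
    if tau_des < -tau_iso:
        return -tau_iso
    return tau_des


def pd_torque(
    gains: FeedbackGains,
    theta_delayed: float,
    omega_delayed: float,
    theta_ref: float,
    t: float,
    t_sm: float,
) -> float:
    """Desired (unsaturated) torque of the delayed PD law at time ``t``.

    Zero during the initial deadtime ``t < t_sm``; afterwards acts on state
    delayed by ``t_sm``:
    ``kp*(theta_ref - theta(t-t_sm)) - kd*omega(t-t_sm) + tau_steadystate``.
    """
    if t < t_sm:
        return 0.0
    return (
        gains.kp * (theta_ref - theta_delayed)
        - gains.kd * omega_delayed
        + gains.tau_steadystate
    )


def bang_bang_torque(plan: FeedforwardPlan, t: float, t_sm: float, tau_iso: float) -> float:
    """Bang-bang torque: 0 in deadtime, then +/-tau_iso switching at t_switch."""
    if t < t_sm:
        return 0.0
    if t < plan.t_switch:
        return plan.direction * tau_iso
    return -plan.direction * tau_iso


def acceleration(task: str, params: AnimalParams, theta: float, tau_act: float) -> float:
    """Angular acceleration (rad/s^2) from the torque balance."""
    return (tau_act + gravity_torque(task, params, theta)) / params.inertia


def steady_state_torque(task: str, params: AnimalParams, theta_ref: float) -> float:
    """Torque countering gravity at the reference target.

    For the swing task this is ``M_limb * g * L_com * sin(theta_ref)`` (the
    limb is held at the raised target against gravity).  The posture target
    is vertical, where gravity exerts no torque, so it is zero.
    """
    return -gravity_torque(task, params, theta_ref)
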