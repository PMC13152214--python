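import math

import numpy as np
import pytest

from neuroscale import (
    AnimalParams,
    FeedbackGains,
    FeedforwardPlan,
    NoRestError,
    TaskConfig,
    Trajectory,
    animal_parameters,
    overshoot,
    peak_torques,
    response_metrics,
    settling_time,
    simulate_feedback,
    simulate_feedforward,
    write_trajectory_csv,
)
from neuroscale.engine import read_trajectory_csv
from oracles import rk4_delayed_pd


class TestSimulateFeedback:
    def test_unforced_plant_stays_at_rest(self, unit_swing_plant):
        cfg = TaskConfig(task="swing", theta0=0.3, omega0=0.0, theta_ref=0.3, movement_size=1.0)
        traj = simulate_feedback(unit_swing_plant, FeedbackGains(0.0, 0.0), cfg)
        assert np.allclose(traj.theta, 0.3, atol=1e-12)
        assert np.allclose(traj.omega, 0.0, atol=1e-12)

    def test_normalized_optimum_settling_time(self, unit_swing_plant, unit_swing_cfg):
        # printed optimum of the unit-delay system: settles in 7.09 delays
        traj = simulate_feedback(
            unit_swing_plant, FeedbackGains(0.1617, 0.6343), unit_swing_cfg
        )
        m = response_metrics(traj, unit_swing_cfg)
        assert m.response_time == pytest.approx(7.09, rel=2e-2)
        assert m.overshoot == 0.0
        assert m.peak_tau_pos == pytest.approx(0.1617, abs=1e-3)
        assert m.peak_tau_neg == pytest.approx(-0.0950, rel=3e-2)

    @pytest.mark.parametrize("task,mass", [("swing", 1.0), ("swing", 1e-3), ("posture", 1.0)])
    def test_agrees_with_fixed_step_oracle(self, task, mass):
        p = animal_parameters(task, mass)
        if task == "swing":
            cfg = TaskConfig.swing()
            gains = FeedbackGains(
                0.1 * p.inertia / p.t_sm**2, 0.5 * p.inertia / p.t_sm, 0.005 * p.tau_iso
            )
        else:
            cfg = TaskConfig.posture(p)
            gains = FeedbackGains(3.5 * p.inertia / p.t_sm**2, 0.6 * p.inertia / p.t_sm)
        traj = simulate_feedback(p, gains, cfg)
        t, th, om = rk4_delayed_pd(p, gains, cfg)
        thi, _ = traj.state_at(t)
        scale = np.max(np.abs(th))
        assert np.max(np.abs(thi - th)) / scale < 1e-4

    def test_saturation_bound_on_all_samples(self):
        p = animal_parameters("swing", 1.0)
        cfg = TaskConfig.swing()
        gains = FeedbackGains(50.0, 1.0)  # strong gains force saturation
        traj = simulate_feedback(p, gains, cfg)
        assert np.all(np.abs(traj.tau_act) <= p.tau_iso * (1 + 1e-12))

    def test_tolerance_convergence(self, unit_swing_plant, unit_swing_cfg):
        g = FeedbackGains(0.1617, 0.6343)
        t1 = settling_time(
            simulate_feedback(unit_swing_plant, g, unit_swing_cfg), unit_swing_cfg
        )
        t2 = settling_time(
            simulate_feedback(
                unit_swing_plant, g, unit_swing_cfg, rtol=5e-9, atol=5e-11
            ),
            unit_swing_cfg,
        )
        assert abs(t1 - t2) / t1 < 1e-3

    def test_movement_size_invariance_linear_plant(self, unit_swing_plant):
        # with no gravity and fixed gains, settling is independent of the
        # common scale of (theta0, theta_ref)
        g = FeedbackGains(0.1617, 0.6343)
        times = []
        for scale in (1.0, 6.0):
            cfg = TaskConfig(
                task="swing",
                theta0=0.0,
                omega0=0.0,
                theta_ref=scale,
                movement_size=scale,
            )
            times.append(settling_time(simulate_feedback(unit_swing_plant, g, cfg), cfg))
        assert times[0] == pytest.approx(times[1], rel=1e-6)

    def test_divergence_flagged_not_raised(self, unit_swing_plant, unit_swing_cfg):
        traj = simulate_feedback(unit_swing_plant, FeedbackGains(80.0, 0.0), unit_swing_cfg)
        assert traj.diverged or not traj.settled_flag
        assert math.isinf(settling_time(traj, unit_swing_cfg))


class TestSimulateFeedforward:
    def test_closed_form_double_integrator(self, unit_swing_cfg):
        # accel 0.25 for t in [1,3], decel after: rest at theta=1 at t=5
        p = AnimalParams(
            task="swing", body_mass=1.0, t_sm=1.0, inertia=1.0, l_com=1.0,
            tau_iso=0.25, limb_mass=0.0, g=0.0,
        )
        traj = simulate_feedforward(p, FeedforwardPlan(t_switch=3.0), unit_swing_cfg)
        assert traj.t[-1] == pytest.approx(5.0, abs=1e-9)
        assert traj.theta[-1] == pytest.approx(1.0, abs=1e-9)
        assert abs(traj.omega[-1]) < 1e-9

    def test_switch_angle_is_midpoint_in_symmetric_case(self, unit_swing_cfg):
        p = AnimalParams(
            task="swing", body_mass=1.0, t_sm=1.0, inertia=1.0, l_com=1.0,
            tau_iso=0.25, limb_mass=0.0, g=0.0,
        )
        traj = simulate_feedforward(p, FeedforwardPlan(t_switch=3.0), unit_swing_cfg)
        th_sw, _ = traj.state_at(3.0)
        assert th_sw[0] == pytest.approx(0.5 * traj.theta[-1], rel=1e-9)

    def test_state_continuity_across_switches(self):
        p = animal_parameters("swing", 1.0)
        cfg = TaskConfig.swing()
        traj = simulate_feedforward(p, FeedforwardPlan(t_switch=0.046), cfg)
        dt = np.diff(traj.t)
        dth = np.abs(np.diff(traj.theta))
        dom = np.abs(np.diff(traj.omega))
        # no jumps in theta or omega anywhere near discontinuity times
        assert np.max(dth) < 10 * np.max(dt) * np.max(np.abs(traj.omega))
        assert np.max(dom) < 10 * np.max(dt) * np.max(np.abs(traj.tau_act)) / p.inertia + 1e-9

    def test_underpowered_plant_never_rests(self):
        # a push the actuator is far too weak to cancel within the safety
        # horizon: velocity never crosses zero
        p = AnimalParams(
            task="posture", body_mass=1.0, t_sm=1.0, inertia=1.0, l_com=1.0,
            tau_iso=1e-6, g=0.0,
        )
        cfg = TaskConfig(task="posture", theta0=0.0, omega0=1.0, theta_ref=0.0, movement_size=1.0)
        with pytest.raises(NoRestError):
            simulate_feedforward(p, FeedforwardPlan(t_switch=3.0, direction=-1), cfg)


class TestSettlingTime:
    def test_first_order_decay_closed_form(self):
        # theta(t) = 1 - exp(-t/tau): leaves the 2% band at tau*ln(50)
        tau_c = 0.7
        t = np.linspace(0, 20, 40001)
        traj = Trajectory.from_arrays(t, 1.0 - np.exp(-t / tau_c), np.exp(-t / tau_c) / tau_c)
        cfg = TaskConfig(task="swing", theta0=0.0, omega0=0.0, theta_ref=1.0, movement_size=1.0)
        assert settling_time(traj, cfg) == pytest.approx(tau_c * math.log(50.0), rel=1e-4)

    def test_inside_band_from_start(self):
        t = np.linspace(0, 10, 101)
        traj = Trajectory.from_arrays(t, np.full_like(t, 1.001), np.zeros_like(t))
        cfg = TaskConfig(task="swing", theta0=0.0, omega0=0.0, theta_ref=1.0, movement_size=1.0)
        assert settling_time(traj, cfg) == 0.0

    def test_undamped_oscillation_never_settles(self):
        t = np.linspace(0, 20, 4001)
        traj = Trajectory.from_arrays(t, np.cos(3 * t), -3 * np.sin(3 * t))
        cfg = TaskConfig(task="swing", theta0=1.0, omega0=0.0, theta_ref=0.0, movement_size=1.0)
        assert math.isinf(settling_time(traj, cfg))

    def test_brief_band_exit_between_samples_detected(self):
        # narrow gaussian bump leaving the band between coarse samples
        t = np.linspace(0, 10, 501)
        th = 1.0 - 0.05 * np.exp(-((t - 6.0) ** 2) / 0.001)
        traj = Trajectory.from_arrays(t, th, np.zeros_like(t))
        cfg = TaskConfig(task="swing", theta0=0.0, omega0=0.0, theta_ref=1.0, movement_size=1.0)
        assert settling_time(traj, cfg) > 5.9

    def test_empty_trajectory_rejected(self):
        traj = Trajectory.from_arrays([], [], [])
        cfg = TaskConfig(task="swing", theta0=0.0, omega0=0.0, theta_ref=1.0, movement_size=1.0)
        with pytest.raises(ValueError):
            settling_time(traj, cfg)


class TestOvershoot:
    def test_monotone_approach_has_none(self):
        t = np.linspace(0, 10, 1001)
        traj = Trajectory.from_arrays(t, 1.0 - np.exp(-t), np.exp(-t))
        cfg = TaskConfig(task="swing", theta0=0.0, omega0=0.0, theta_ref=1.0, movement_size=1.0)
        assert overshoot(traj, cfg) == 0.0

    def test_peak_past_target_measured(self):
        t = np.linspace(0, 10, 1001)
        th = 1.0 + 0.01 * np.sin(t) * np.exp(-t)
        traj = Trajectory.from_arrays(t, th, np.zeros_like(t))
        cfg = TaskConfig(task="swing", theta0=0.0, omega0=0.0, theta_ref=1.0, movement_size=1.0)
        peak = float(np.max(th) - 1.0)
        assert overshoot(traj, cfg) == pytest.approx(peak, rel=1e-3)

    def test_critically_damped_step_has_none(self):
        # theta = 1 - (1 + w t) exp(-w t), monotone to 1
        w = 2.0
        t = np.linspace(0, 15, 2001)
        th = 1.0 - (1.0 + w * t) * np.exp(-w * t)
        om = w**2 * t * np.exp(-w * t)
        traj = Trajectory.from_arrays(t, th, om)
        cfg = TaskConfig(task="swing", theta0=0.0, omega0=0.0, theta_ref=1.0, movement_size=1.0)
        assert overshoot(traj, cfg) == 0.0

    def test_posture_opposite_side_excursion(self):
        t = np.linspace(0, 10, 1001)
        th = 0.1 * np.sin(t) * np.exp(-0.5 * t)  # dips negative after the push
        traj = Trajectory.from_arrays(t, th, np.zeros_like(t))
        cfg = TaskConfig(task="posture", theta0=0.0, omega0=1.0, theta_ref=0.0, movement_size=1.0)
        assert overshoot(traj, cfg) == pytest.approx(float(np.max(-th)), rel=1e-3)


class TestPeakTorques:
    def test_zero_torque(self):
        t = np.linspace(0, 1, 11)
        traj = Trajectory.from_arrays(t, t, t, tau_act=np.zeros_like(t), tau_iso=2.0)
        assert peak_torques(traj) == (0.0, 0.0, 0.0)

    def test_fraction_of_capacity(self):
        t = np.linspace(0, 1, 101)
        tau = 0.5 * np.sin(2 * np.pi * t)
        traj = Trajectory.from_arrays(t, t, t, tau_act=tau, tau_iso=2.0)
        hi, lo, frac = peak_torques(traj)
        assert hi == pytest.approx(0.5, rel=1e-3)
        assert lo == pytest.approx(-0.5, rel=1e-3)
        assert frac == pytest.approx(0.25, rel=1e-3)


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path, unit_swing_plant, unit_swing_cfg):
        traj = simulate_feedback(
            unit_swing_plant, FeedbackGains(0.1617, 0.6343), unit_swing_cfg
        )
        path = write_trajectory_csv(traj, tmp_path / "traj.csv")
        back = read_trajectory_csv(path)
        assert np.allclose(back.theta, traj.theta)
        assert np.allclose(back.t, traj.t)
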