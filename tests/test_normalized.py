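import math

import numpy as np
import pandas as pd
import pytest

from neuroscale import (
    FeedbackGains,
    classify_regions,
    normalized_task,
    simulate_feedback,
    simulate_normalized,
    sweep_force_capacity,
    unit_plant,
)
from neuroscale.engine import response_metrics
from neuroscale.normalized import NormalizedConfig, SweepResult

PRINTED_GAINS = (0.1617, 0.6343)


class TestUnitPlant:
    def test_gravity_free_and_dimensionless(self):
        p = unit_plant()
        assert p.inertia == 1.0 and p.t_sm == 1.0
        assert p.g == 0.0 and math.isinf(p.tau_iso)

    def test_capacity_forwarded(self):
        assert unit_plant(0.12).tau_iso == 0.12

    def test_bad_capacity_rejected(self):
        with pytest.raises(ValueError):
            NormalizedConfig(tau_iso_bar=0.0)


class TestSimulateNormalized:
    def test_zero_gains_never_move(self):
        cfg = NormalizedConfig(gains_bar=(0.0, 0.0))
        traj = simulate_normalized(cfg)
        assert np.allclose(traj.theta, 0.0)

    def test_moderate_capacity_identical_to_unconstrained(self):
        # the unconstrained optimum peaks at ~0.16, so a 0.25 limit is
        # never touched and the trajectories coincide
        free = simulate_normalized(NormalizedConfig(gains_bar=PRINTED_GAINS))
        capped = simulate_normalized(
            NormalizedConfig(tau_iso_bar=0.25, gains_bar=PRINTED_GAINS)
        )
        assert np.allclose(free.theta, capped.theta, atol=1e-10)
        task = normalized_task()
        m_free = response_metrics(free, task)
        m_capped = response_metrics(capped, task)
        assert m_free.response_time == pytest.approx(m_capped.response_time, rel=1e-6)

    def test_peak_torque_equals_proportional_gain(self):
        traj = simulate_normalized(NormalizedConfig(gains_bar=PRINTED_GAINS))
        m = response_metrics(traj, normalized_task())
        assert m.peak_tau_pos == pytest.approx(PRINTED_GAINS[0], abs=1e-3)

    def test_posture_variant_returns_to_rest(self):
        # unit velocity push on the gravity-free unit plant; a damped PD
        # settles the velocity band within the horizon
        cfg = NormalizedConfig(gains_bar=(0.16, 0.63), task_variant="posture")
        traj = simulate_normalized(cfg)
        import math

        from neuroscale import settling_time

        ts = settling_time(traj, normalized_task("posture"))
        assert math.isfinite(ts)

    def test_dimensional_equivalence_of_normalization(self):
        # simulate a dimensional gravity-free plant and the unit plant at
        # the correspondingly rescaled gains: identical normalized settling
        from neuroscale import AnimalParams, TaskConfig

        inertia, t_sm, theta_r = 2.52e-4, 0.031, 0.5236
        p = AnimalParams(
            task="swing", body_mass=1.0, t_sm=t_sm, inertia=inertia, l_com=1.0,
            tau_iso=math.inf, limb_mass=0.0, g=0.0,
        )
        cfg = TaskConfig(
            task="swing", theta0=0.0, omega0=0.0, theta_ref=theta_r, movement_size=theta_r
        )
        kp = PRINTED_GAINS[0] * inertia / t_sm**2
        kd = PRINTED_GAINS[1] * inertia / t_sm
        m_dim = response_metrics(simulate_feedback(p, FeedbackGains(kp, kd), cfg), cfg)
        m_norm = response_metrics(
            simulate_normalized(NormalizedConfig(gains_bar=PRINTED_GAINS)),
            normalized_task(),
        )
        assert m_dim.response_time / t_sm == pytest.approx(m_norm.response_time, rel=1e-6)


class TestSweep:
    def test_two_point_sweep_regions(self):
        # 0.20 is above the unconstrained peak (high region); 0.12 clips
        # the positive torque only (middle region)
        sweep = sweep_force_capacity([0.12, 0.20])
        tb = sweep.table
        assert list(tb["region"]) == ["middle", "high"]
        high_row = tb[tb["tau_iso_bar"] == 0.20].iloc[0]
        assert high_row["t_resp_bar"] == pytest.approx(7.09, rel=0.02)
        mid_row = tb[tb["tau_iso_bar"] == 0.12].iloc[0]
        assert mid_row["saturated_pos"] and not mid_row["saturated_neg"]
        assert mid_row["t_resp_bar"] >= high_row["t_resp_bar"] - 1e-6

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_force_capacity([0.2, 0.1])
        with pytest.raises(ValueError):
            sweep_force_capacity([])


class TestClassifyRegions:
    def _table(self, rows):
        cols = [
            "tau_iso_bar", "kp_bar", "kd_bar", "t_resp_bar",
            "peak_pos", "peak_neg", "saturated_pos", "saturated_neg", "feasible",
        ]
        tb = pd.DataFrame(rows, columns=cols)
        tb["region"] = "x"
        return SweepResult(table=tb)

    def test_boundaries_from_flags(self):
        rows = [
            (0.05, 1, 1, 10, 0.05, -0.05, True, True, True),
            (0.10, 1, 1, 9, 0.10, -0.08, True, False, True),
            (0.15, 1, 1, 8, 0.15, -0.09, True, False, True),
            (0.20, 1, 1, 7, 0.16, -0.095, False, False, True),
        ]
        high, mid, low = classify_regions(self._table(rows))
        assert (high, mid, low) == (0.15, 0.05, 0.05)

    def test_all_unsaturated_single_high_region(self):
        rows = [
            (0.2, 1, 1, 7, 0.16, -0.09, False, False, True),
            (0.25, 1, 1, 7, 0.16, -0.09, False, False, True),
        ]
        high, mid, low = classify_regions(self._table(rows))
        assert math.isnan(high) and math.isnan(mid)
        assert low == 0.2

    def test_non_monotone_pattern_warns(self):
        rows = [
            (0.1, 1, 1, 9, 0.1, -0.05, True, False, True),
            (0.15, 1, 1, 8, 0.1, -0.05, False, False, True),
            (0.2, 1, 1, 8, 0.2, -0.05, True, False, True),
        ]
        with pytest.warns(UserWarning):
            classify_regions(self._table(rows))
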