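"""Independent brute-force integrators used to cross-check the engine.

The fixed-step RK4 method-of-steps integrator below shares no code with
the adaptive engine: it marches the delayed-PD closed loop on a uniform
grid of ``n_per`` steps per deadtime and linearly interpolates the stored
past trajectory for the delayed-state lookups at half-steps.
"""

from __future__ import annotations

import numpy as np


def rk4_delayed_pd(params, gains, cfg, horizon_mult: int = 20, n_per: int = 2000):
    """Fixed-step RK4 integration of the delayed-PD loop.

    Returns (t, theta, omega) arrays on the uniform grid.
    """
    T = params.t_sm
    h = T / n_per
    n_tot = horizon_mult * n_per
    th = np.empty(n_tot + 1)
    om = np.empty(n_tot + 1)
    th[0], om[0] = cfg.theta0, cfg.omega0
    if params.task == "swing":
        cg = -params.limb_mass * params.g * params.l_com
    else:
        cg = params.body_mass * params.g * params.l_com
    inv_i = 1.0 / params.inertia
    tau_iso = params.tau_iso

    def delayed(idx: float):
        i0 = int(np.floor(idx))
        frac = idx - i0
        i1 = min(i0 + 1, n_tot)
        return th[i0] * (1 - frac) + th[i1] * frac, om[i0] * (1 - frac) + om[i1] * frac

    def f(t, y):
        if t < T:
            tau = 0.0
        else:
            thd, omd = delayed((t - T) / h)
            tau = (
                gains.kp * (cfg.theta_ref - thd)
                - gains.kd * omd
                + gains.tau_steadystate
            )
            tau = min(max(tau, -tau_iso), tau_iso)
        return np.array([y[1], (tau + cg * np.sin(y[0])) * inv_i])

    for i in range(n_tot):
        t = i * h
        y = np.array([th[i], om[i]])
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        th[i + 1], om[i + 1] = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return np.arange(n_tot + 1) * h, th, om


def ols_loglog(masses, values):
    """Closed-form OLS on (log10 m, log10 v): returns (coefficient, exponent)."""
    x = np.log10(np.asarray(masses, dtype=float))
    y = np.log10(np.asarray(values, dtype=float))
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    b = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    a = (sy - b * sx) / n
    return 10.0**a, b
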