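# Methods

## The models

`neuroscale` studies how fast terrestrial mammals of different sizes can
reject a perturbation when their neural control is limited by two
factors: the sensorimotor delay `t_sm` (all latency between detecting a
perturbation and producing muscle force, modeled as a pure deadtime plus
delayed state feedback) and the muscle force capacity `tau_iso` (maximum
isometric torque, modeled as symmetric actuator saturation).

Two single-degree-of-freedom perturbation tasks are modeled:

* **swing task** — a forelimb, modeled as a distributed-mass pendulum
  hanging from the shoulder, is repositioned from rest at -15 deg to rest
  at +15 deg after a trip.  Gravity is restoring
  (`tau_g = -M_limb g L_com sin(theta)`).
* **posture task** — the whole body, modeled as an inverted point-mass
  pendulum on a leg-length lever, is returned to rest at vertical after
  an impulsive push that sets the initial angular velocity to
  `omega0 = 0.21 * sqrt(g / L)` (a Froude-scaled, i.e. dynamically
  similar, push).  Gravity is destabilizing (`tau_g = +M g L sin(theta)`).

Two controllers are compared on each task:

* **delayed PD feedback** — desired torque
  `kp (theta_ref - theta(t - t_sm)) - kd omega(t - t_sm) + tau_ss`, zero
  during the initial deadtime, saturated at `tau_iso`.  The steady-state
  torque `tau_ss` is fixed analytically to the torque countering gravity
  at the target (it is not a free parameter); it is zero for the posture
  task.  The gains are optimized for the fastest 2% settling time subject
  to zero overshoot.
* **minimum-time feedforward** — the time-optimal open-loop benchmark:
  after the deadtime, bang-bang torque at +/-`tau_iso` with a single
  switch time, chosen so the plant comes to rest exactly at the target.
  Response time is the elapsed time to rest.

Response time is the **settling time**: the last time the monitored
signal leaves a band of half-width 2% of the movement.  The swing task
monitors the angle around the target (band 2% of the 30-deg movement);
the posture task monitors the angular velocity around zero (band 2% of
the perturbation velocity `|omega0|` — the band normalizer is a design
choice; the perturbation magnitude is the natural movement-size analogue).
Settling uses the last-exit convention standard in control theory.

## Animal-size parameterization

All physical and neural parameters follow allometric power laws
`parameter = a * M^b` shipped as a CSV table (one row per parameter:
task, name, coefficient, exponent, units).  Coefficients are the values
for a 1 kg animal; times are tabulated in ms and converted to strict SI
at ingestion.  The laws cover the sensorimotor delay, segment mass,
inertia and length, and maximum isometric torque for both tasks, plus
the swing duration at maximum sprint speed (the time available for a
swing correction).  The grid of study is ten body masses: eight
log-spaced decades from 1 g to 10 t plus 5 g and 5 t.  This generator
*is* the study's input data; there is no external dataset.

Two tabulated choices deserve note:

* the posture `tau_iso` law (3.41 N m at 1 kg) is taken as already
  aggregating the plantarflexors of all four legs; it is not multiplied
  by four again.
* the dimensionless perturbation velocity is read as COM speed
  `v = 0.21 sqrt(g L)` (so `omega0 = 0.21 sqrt(g/L)`); the alternative
  reading `v = sqrt(0.21 g L)` is selectable
  (`froude_velocity(..., convention="squared")`) but produces
  feedforward times far from the tabulated results, supporting the
  default.

## Numerical integration

The feedback loop is a delay differential equation.  It is integrated by
the method of steps: the horizon (20 deadtimes) is split at integer
multiples of `t_sm`, where the solution has derivative discontinuities,
and each interval is integrated with an adaptive explicit Runge-Kutta
scheme (`scipy.integrate.solve_ivp`, RK45, rtol 1e-8, atol 1e-10) with
dense output; the delayed state inside interval `k` is evaluated from
interval `k-1`'s dense interpolant.  History before t = 0 is the constant
initial state.  Blow-ups set a `diverged` flag instead of raising so
optimizers can penalize them.  The engine agrees with an independent
fixed-step RK4 method-of-steps integrator (2000 steps per deadtime) to
better than 1e-4 relative error in angle, and halving the tolerances
changes settling times by far less than 0.1%.

Feedforward runs are ordinary ODEs integrated phase by phase (deadtime,
first torque phase, second torque phase), terminated at the first
zero-crossing of angular velocity after the switch (located by scipy's
event root-finding on dense output).  "At rest" is that zero-crossing,
not a small-velocity threshold, matching the bang-bang structure.

Settling is computed from a dense trajectory sampling (4001 points)
refined by root-finding on the interpolants.  Because the optimal
response typically *grazes* the settling band, every near-band local
maximum of the error signal is refined before the sampled answer is
trusted; otherwise the optimizer exploits band exits that fall between
samples.  Overshoot is the angle excursion past the target in the
direction of motion (posture: past vertical on the side opposite the
push), refined the same way.

## Optimization

**Feedback gains.**  Nelder-Mead in log-gain space with a deterministic
multi-start list: the dimensional analogue of the normalized optimum
(`kp ~ 0.16 I / t_sm^2`, `kd ~ 0.63 I / t_sm`) plus a log-spaced product
grid spanning about a factor 8 below to 4 above it in `kp` and 2.8 either
way in `kd` (gravity shifts the optimum well away from the analogue).
The best starts are refined and the winner polished with tight simplex
tolerances; the settling objective is kinked with many near-equal local
minima, so the polish also restarts from the analogue.  Zero overshoot
is enforced as an exact penalty with tolerance 1e-6 of the movement:
settling time is steeply sensitive to permitted overshoot near the
boundary (slope ~1e3 in normalized units), and at looser tolerances the
"constrained optimum" drifts measurably away from the true zero-overshoot
optimum.  Non-settling runs receive a finite, ordered penalty (horizon
plus overshoot) so the simplex can escape.  Posture runs must also end
with the angle back at vertical (within 2% of its peak excursion):
velocity-band settling alone admits a degenerate solution in which a weak
controller (kp below the gravitational stiffness `M g L`) leaves the body
hanging at a quasi-static tilt.  In the scaling pipeline each size is
additionally warm-started from its neighbor's optimum rescaled to
normalized gain units, which stabilizes the force-limited large-animal
posture optima.  The search contains no randomness; the seed is recorded
for provenance.

**Switch time.**  The rest-position residual (stopping angle minus
target) is monotone in the switch time, so the switch is found by Brent
root-finding (absolute tolerance 1e-9 s) after a geometric scan upward
from the deadtime brackets the root.  Switch times too early to ever
stop the plant (e.g. posture switches before the push is cancelled) fail
to rest and are skipped during bracketing.

**Integral control** is deliberately not implemented; the steady-state
torque alternative needs fewer parameters and the package mirrors that
choice.

## The normalized model

Dividing the gravity-free swing loop by `I theta_r / t_sm^2` leaves a
single free parameter, the normalized force capacity
`tau_iso_bar = tau_iso t_sm^2 / (I theta_r)`.  The package reproduces its
landmark values: unconstrained optimal gains (~0.162, ~0.634), fastest
settling ~7.09 delays, peak accelerating torque equal to `kp_bar`, peak
braking torque ~ -0.095.  Sweeping `tau_iso_bar` with per-point gain
re-optimization (warm-started high-to-low) classifies three regions:
delay-limited above ~0.161 (no saturation; settling constant), a middle
region where only the accelerating torque clips, and a low region below
~0.08 where braking clips too and settling grows steeply.  A saturation
flag uses a 1e-6 relative margin on the peak torque.  The normalized
posture variant (unit perturbation velocity) is provided but the
normalization constant for its dimensional counterpart is not pinned
down; it is flagged experimental.

## Problem sizes in the test suite

The full pipeline (10 sizes x 2 tasks x 2 controllers, plus the 0.001-step
capacity sweep) is exercised by `scripts/acceptance.py`.  The test suite
runs the same computations at reduced problem sizes chosen to preserve
the fitted quantities: scaling checks use a 4-mass subset (1 g, 100 g,
10 kg, 10 t — the fits are near-exact power laws, so the subset fit
matches the full-grid fit to well under a percent), and the sweep check
uses a coarse grid plus 0.001-step refinement near the detected
boundary.

## Known limitations

* No Hill-type muscle dynamics, pennation, or velocity-dependent force
  limits; the delay already lumps electromechanical and force-generation
  lags.
* Single-joint rigid-body plants; no multi-joint coordination, sensor
  noise, or continuous perturbations.
* The gain optimizer certifies no global optimum; the objective has many
  near-equal local minima (visible as small scatter of fitted gain laws).
* Below a normalized capacity of ~0.009 the sweep reports empirical
  infeasibility (no zero-overshoot settle within the horizon); the
  package does not attempt to characterize that regime further.
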