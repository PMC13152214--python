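# Sign and angle conventions

Angles are radians everywhere inside the library; degrees appear only at
the CLI boundary (`--movement-deg`).

## Swing task (hanging pendulum forelimb)

- zero angle: limb pointing vertically **down**; counter-clockwise positive.
- plant: `I_limb * theta_dd = tau_act + tau_gravity`,
  `tau_gravity = -M_limb * g * L_com * sin(theta)` (restoring).
- default movement: rest at -15 deg to rest at +15 deg.
- positive torque and the bang-bang first phase push toward the (positive)
  target.
- steady-state torque: `M_limb * g * L_com * sin(theta_ref)` holds the limb
  at the raised target.
- settling signal: angle, band half-width 2% of the full movement.

## Posture task (inverted point-mass pendulum)

- zero angle: body axis vertically **up**; counter-clockwise positive.
- plant: `I * theta_dd = tau_act + tau_gravity`,
  `tau_gravity = +M * g * L * sin(theta)` (destabilizing), `I = M L^2`.
- perturbation: impulsive push setting `omega0 = froude * sqrt(g / L)`
  (dimensionless velocity referred to the COM speed `v = froude *
  sqrt(g L)`); position unchanged; target is rest at vertical.
- bang-bang first phase opposes the push: `direction = -sign(omega0)`.
- settling signal: angular velocity, band half-width 2% of `|omega0|`.
- overshoot: angle excursion past vertical on the side opposite the push.

## Torques

- `tau_des` is the controller output before saturation; `tau_act` is the
  clamp of `tau_des` to `[-tau_iso, +tau_iso]`.
- Feedback torque is zero during the initial deadtime `t < t_sm` and acts
  on state delayed by `t_sm` afterwards.
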