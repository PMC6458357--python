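# Methods

## The model

The runner is a planar rigid body of mass `m`, moment of inertia `I_G = m r_g²`
about its centre of mass G, and leg length `r_l`. All quantities are
nondimensionalized with `m = g = r_l = 1`, so speeds are in units of
`sqrt(g r_l)` and time in `sqrt(r_l / g)`. A step alternates:

- **Flight** — drag-free projectile motion: `x'' = 0`, `y'' = -1`, `phi'' = 0`.
- **Stance** — instantaneous, at a contact point P one leg length from G.
  Stance is a passive collision followed by an active push-off:
  1. *Passive collision*: the contact-point velocity is rescaled by two
     coefficients of restitution, `v_P,t -> eps_t v_P,t` tangentially and
     `v_P,n -> -eps_n v_P,n` normally, with angular momentum about P conserved
     (the collision impulse acts at P). These three scalar constraints
     determine the post-collision COM velocity and spin uniquely.
  2. *Active push-off*: a linear impulse `J` applied at P plus an angular
     impulse `J_phi` at G, chosen once so that the gait on flat ground is
     exactly periodic with take-off velocity `(v_x0, v_y0)` and zero spin, and
     then held fixed on every terrain (no step-to-step feedback). The closed
     form is

         J_t = I_G (1 - eps_tc) v_x0 / (1 + I_G),    J_n = (1 - eps_n) v_y0,

     with `J_phi = 0`: the moment of `J` about G exactly cancels the
     collisional spin, so angular periodicity costs no extra impulse. At
     `eps_n = eps_tc = 1` the push-off vanishes identically.

Tangential control distinguishes two strategies. The **open-loop** runner has
no sensory information and aims for the contact-point speed it would see on
flat ground at the nominal gait, so its post-collision tangential contact
velocity is `eps_tc * v_x0` regardless of the actual approach speed
(equivalently `eps_t = eps_tc v_x0 / v_P,t⁻`, which may exceed 1). The
**anticipatory** runner knows the local tangent perfectly and realizes
`eps_t = eps_tc` exactly. Control noise replaces `eps_tc` by
`eps_tc + delta_eps_t * eta`, `eta ~ U[-1, 1]`, one fresh draw per step,
before the open-loop ratio is applied.

The push-off impulse vector can be held fixed in the frame of the local
terrain tangent/normal (**terrain-fixed**, the default, equivalent to a
body-centric plan) or in laboratory axes (**laboratory-fixed**); both are
implemented and coincide on flat ground.

**Failure** is declared when the orientation at touchdown exceeds the
tip-over threshold (`|phi| > phi_tol`, orientational) or when the forward
speed after push-off drops below `v_stop = 0.01` (translational). Steps to
failure counts successfully completed steps before the failure event (a
runner failing at its first touchdown scores 0); the long anticipatory means
are insensitive to this choice, and the short open-loop means match the
reported statistics under it.

## Terrain and contact

Rough terrains are piecewise-linear interpolations of i.i.d. node heights on
a grid of spacing `lambda = 0.1`; step-like terrains are piecewise constant
per cell, with the risers excluded as contact zones. Height families:
uniform (support rescaled to `[-range/2, +range/2]`), beta(1.9, 2.3)
(support rescaled to the nominal range and centred), and von Mises(kappa=6).
The von Mises family is rescaled to match the *height variance* of the
uniform family at the same nominal range (`sd = range/sqrt(12)`) rather than
its support: a concentrated distribution squeezed to the same support would
carry several times less slope variance and could not reproduce the
shape-insensitivity of the failure statistics that variance matching yields.

Touchdown is the earliest time on the **descending branch** of the flight
parabola (from the apex onward) at which the unit disc about G touches the
contactable terrain elements; grazes against rising ground during the ascent
are not stance events. The root is bracketed by marching at `lambda/4` of
horizontal travel and polished by bisection to 1e-13 in time. A take-off
aimed into rising ground that never separates is assigned an immediate
touchdown once its penetration deepens 1e-4 below the take-off clearance.

The contact geometry keeps the leg along the contact normal: `r_PG = -n̂`,
with `n̂` perpendicular to the segment for interior contacts and radial
across the rounded-corner fan at nodes. This choice is what makes an
`eps_t = 1` collision exactly spin-free on arbitrary local geometry — the
defining property of the perfectly anticipatory runner — and it distributes
corner-fan contact slopes continuously between the adjacent segment slopes.
For step-like terrains the contact tangent always comes from the flat
landing tread, which decouples forward and vertical dynamics; a leading
tread edge whose level sits clearly above the disc bottom is flagged as a
riser-face strike. The API-level `terrain_query` exposes the complementary
node-slope smoothing (linear blend of adjacent segment gradients within 1%
of the spacing around each node). Residual geometric penetration after a
corner push-off (offset-curve vs polyline mismatch, O(1e-4)) is projected
out along the clearance gradient.

Grazing touchdowns with a separating contact-point normal velocity (possible
at corner fans when the body spins) receive no normal collision impulse —
the continuous limit of `-eps_n v_P,n` as `v_P,n -> 0⁻` — while tangential
control still applies.

## Monte Carlo

Each trial draws a fresh terrain and, when noise is on, a fresh noise
stream, from `SeedSequence((seed, *key, trial, 0|1))`, so results are
deterministic given the seed and independent of execution order or ensemble
size (the first trials of a larger ensemble are bit-identical to a smaller
one). Trials are stepped by a numba-compiled kernel that mirrors the
pure-Python reference path operation for operation; single-step agreement is
asserted in the tests, and whole trajectories may diverge only through
chaotic amplification of last-ulp library differences. Censored trials
(surviving `max_steps = 1000`) are excluded from the mean/sd and reported as
a separate fraction; at the human-like parameters none survive that long.
Reference ensembles use `M = 10^4` trials, giving standard errors of a few
percent of the means.

## Linear stability

The Poincaré section is the apex of the aerial phase (`v_y = 0`), with the
state `psi = (x, y, phi, v_x, omega)` measured in a frame translating at
`v_x0`; the periodic gait is the fixed point `psi* = 0`. On flat ground no
ascending contact exists, so the apex-to-apex composition is exact. The 5×5
Jacobian `T` is computed by central differences (default step 1e-6) with a
step-halving consistency check at 1e-6 entrywise; the rank threshold used
for multiplicities scales with the finite-difference noise floor
(`max(1e-8 ||T||, 5e-12/fd_step)`), which keeps the integer multiplicities
invariant over `fd_step` in [1e-7, 1e-4] and over two decades of threshold.

The unity eigenvalue is defective: algebraic multiplicity 3 and geometric 2
for `eps_tc < 1` (both strategies), and 4/2 at `eps_tc = 1` where forward
speed decouples from spin. Jordan chains are extracted from the null spaces
of `(T - I)^k`; perturbations along a generalized eigenvector grow *linearly*
with the number of steps (`Tⁿ v = v + n (T - I) v`) even though no
eigenvalue exceeds 1 in magnitude — numerically the defective pair splits by
about the square root of the Jacobian error, so spectral-radius checks use a
1e-3 guard band. A vertical-height perturbation decays with factor `eps_n`
per step.

## Scaling law

One flat-gait stance on a uniform slope `theta` (nominal landing velocity,
contact tangent inclined by `theta`) yields a take-off spin `omega⁺` and
vertical speed `v_y⁺`; the orientation accumulated over the following aerial
phase is `phi_step = 2 v_y⁺ omega⁺`. The mean steps to orientational failure
scales as `N ~ phi_tol / phi_step`, and this single dimensionless group
collapses ensembles across independent variations of `I_G`, `v_y0`,
`eps_n`, `eps_tc` and `phi_tol` (rank correlation ~0.97 across 24 parameter
sets at `M = 500` each). The sweep samples `1 - eps_tc` log-uniformly down
to 0.01 — 0.99 being the largest tangential restitution at which
orientational failures still dominate — so that survival spans decades and
the primary signal dominates secondary parameter effects. The collapse abscissa evaluates
`phi_step` at the terrain's r.m.s. slope angle,
`atan(sqrt(2 Var(h))/lambda)` (about 0.24 rad for the reference terrain);
the rank-correlation criterion is insensitive to this choice. Runners with
`eps_tc = 1` have `phi_step = 0` (no orientational failures) and are
excluded.

The small-slope series implemented in `phi_series` uses the printed
coefficients; their `eps_n`- and `eps_tc`-dependent parts agree with the
simulated stance exactly at every `I_G`, while the collision-independent
quadratic sub-term agrees in the small-`I_G` limit (the regime in which the
downstream closed forms are quoted). Third-order convergence of series vs
stance is therefore verified at `I_G = 1e-4`; at the human-like `I_G = 0.17`
the leading order and the `eps_n` sensitivity are verified instead, and the
residual is O(`I_G theta²`).

`gravity_angular_impulse` estimates the error of the instantaneous-stance
idealization: over a finite stance the moment of body weight about P changes
the angular momentum by at most `sin²(beta)/(2 v_x0)` for touchdown angle
`beta` (the fully asymmetric stance admissible under a unit leg, whose
horizontal COM offset cannot exceed `sin beta`; a symmetric stance
integrates to zero), about 0.06 at 20°, producing a single-step orientation
change below 0.01 — negligible against the terrain-induced perturbations.

## What the synthetic terrain does and does not emulate

The generator reproduces uncorrelated height/slope roughness at a single
correlation length `lambda` much shorter than a stride, which is what makes
successive stance perturbations i.i.d. and the failure dynamics diffusive.
It does not emulate correlated or fractal terrain spectra, spatial filtering
by a finite foot, compliant ground, or three-dimensional slope components;
passing tests therefore speak to the propagation of idealized impulsive
perturbations, not to any specific natural terrain.

## Numerical choices

- Touchdown bisection to 1e-13 in time; flat-ground periodicity holds to
  1e-12 per step in every state component.
- Candidate contact elements within ±1.05 of the COM abscissa (the disc
  cannot touch farther elements at sub-vertical slopes).
- Collision solved as a 3×3 linear system in the reference path and in
  closed form (leg along the normal) in the kernel; both reproduce the
  collision constraints to 1e-12.
- Ensembles pre-size terrains to 2.5× the nominal stride times `max_steps`
  and retry with doubled extent in the rare case a trial outruns it.
- Problem sizes: `M = 10^4` trials for reference ensembles, `M = 1000` × 24
  parameter sets for the collapse, 6-point noise grid at `M = 10^4`; these
  give statistical errors of a few percent, well below the effects being
  measured.

## Known limitations

- The fully elastic anticipatory runner (`eps_n = eps_tc = 1`) conserves
  energy exactly, so its slowdown is a pure direction random walk with a
  heavy-tailed steps-to-failure distribution; its ensemble mean needs ~10^4
  trials before the standard error drops below a few percent.
- `phi` is not wrapped; the orientational check compares `|phi|` directly to
  `phi_tol` at touchdown only (not continuously during flight).
- Corner contacts make the return map only piecewise smooth; the
  linearization is taken at the flat-ground fixed point where the map is
  smooth, and the step-halving check guards against accidental
  non-smoothness.
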