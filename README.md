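# runsim — impulsive-stance running on rough terrain

`runsim` simulates and analyses a minimal sagittal-plane model of running on
uneven ground, for researchers in locomotion biomechanics and legged-robot
design who want to understand how terrain slope and height perturbations
destabilize a runner that uses no within-step feedback.

The runner is a planar rigid body (mass `m`, moment of inertia `I_G`, leg
length `r_l`; units with `m = g = r_l = 1`). Each step is ballistic flight
plus an instantaneous stance: a passive collision that rescales the
contact-point velocity by restitution coefficients `eps_n` (normal) and
`eps_t` (tangential), followed by a fixed push-off impulse

    J = ( I_G (1 - eps_tc) v_x0 / (1 + I_G),  (1 - eps_n) v_y0 )

applied at the contact point, chosen once so the flat-ground gait with
take-off velocity `(v_x0, v_y0)` is exactly periodic and then reused on
every terrain. Tangential control is either *open-loop* (assumes flat
ground at nominal speed: `eps_t = eps_tc v_x0 / v_P,t⁻`) or *anticipatory*
(perfect knowledge of the local tangent: `eps_t = eps_tc`). A runner fails
*orientationally* when its pitch at touchdown exceeds `phi_tol`, or
*translationally* when its forward speed drops below 0.01.

The package provides:

- the stance/flight mechanics and a fast Monte Carlo engine for
  steps-to-failure statistics on random piecewise-linear ("rough") and
  piecewise-constant ("step-like") terrains;
- the apex-to-apex Poincaré return map, its 5×5 linearization, and the
  Jordan structure of its defective unity eigenvalue (the mechanism behind
  the linear-in-steps instability despite spectral radius 1);
- the one-step orientation change `phi_step = 2 v_y⁺ omega⁺` and the
  stability scaling law `N ~ phi_tol / phi_step` that collapses failure
  statistics across body plans.

## Worked example

Ten thousand open-loop runners with human-like parameters (`I_G = 0.17`,
`eps_n = 0.63`, `eps_tc = 0`, `phi_tol = pi/6`, take-off velocity
`(0.96, 0.26)`) on rough terrain with node heights `U(-0.03, 0.03)` at
spacing 0.1:

```python
from runsim import RunnerParams, TerrainSpec, run_ensemble

stats = run_ensemble(RunnerParams(), TerrainSpec(), M=10_000, seed=1)
print(f"mean steps to failure: {stats.mean_steps:.1f} +- {stats.sd_steps:.1f} (sd)")
print(stats.failure_mode_fractions)
```

```
mean steps to failure: 9.3 +- 4.6 (sd)
{'none': 0.0, 'orientational': 1.0, 'translational': 0.0}
```

The runner tumbles after about ten steps, essentially always by pitching
past the tip-over threshold. Switching to the perfectly anticipatory
strategy (`strategy="anticipatory", eps_tc=1.0`) eliminates tumbling
entirely — every failure becomes a loss of forward speed, after ~75 steps
on average — because an `eps_t = 1` collision with the leg along the local
terrain normal leaves the body spin-free on any slope.

The same asymmetry shows up in the linearized return map:

```sh
runsim linearize --eps-tc 1.0 --out linmap.json
# unity eigenvalue: algebraic multiplicity 4, geometric 2; map -> linmap.json
```

The unity eigenvalue is defective (only two eigenvectors: translation and
orientation shifts), so perturbations along its generalized eigenvectors
grow linearly with the number of steps — the runner is unstable even though
no Floquet multiplier exceeds 1.

Other entry points: `runsim simulate` (single-trial trace CSV),
`runsim montecarlo` (ensemble statistics JSON), `runsim sweep` (parameter
grids), `runsim scaling` (the `phi_tol/phi_step` collapse table),
`runsim terrain` (terrain CSV export). All accept a YAML/JSON config file
(`--config`) whose omitted fields default to the human-like parameter set.

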