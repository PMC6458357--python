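"""The one-step orientation change phi-step and the stability scaling law.

A runner with the periodic flat-ground gait that lands once on a uniform
slope theta takes off with a slightly rotated state; the orientation it
accumulates over the following aerial phase is

    phi_step = 2 * v_y+ * omega+

(aerial time 2 v_y+ at angular rate omega+).  Orientational failure needs
|phi| to reach phi_tol, and because perturbations accumulate diffusively
with a linearly growing mean, the mean steps to failure scales as
N ~ phi_tol / phi_step.  This single dimensionless group collapses the
Monte Carlo failure statistics across independent variations of inertia,
take-off velocity, collision parameters and tolerance.

Small-slope series (human-like, I_G << 1, anticipatory strategy):

    phi_an ~ 2 v_y0^2 (1 - eps_tc) theta
             + (1 - eps_tc)(2 eps_n + 3) v_x0 v_y0 theta^2

so perfect tangential-collision avoidance (eps_tc = 1) suppresses the
orientation change at every order shown, while the open-loop leading term
2 v_y0^2 theta / (1 + I_G) is independent of both collision parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import (
    BodyState,
    ContactEvent,
    Phase,
    RunnerParams,
    Strategy,
    apply_pushoff,
    collision_with_targets,
    contact_point_velocity,
    pushoff_impulse,
)
from .montecarlo import run_ensemble
from .terrain import TerrainSpec, rms_slope_angle

__all__ = [
    "ScalingRecord",
    "one_step_phi",
    "phi_series",
    "predict_steps",
    "collapse_experiment",
    "gravity_angular_impulse",
]


@dataclass
class ScalingRecord:
    """One parameter set's entry in the scaling-collapse table."""

    params: RunnerParams
    theta: float
    phi_step: float
    N_pred: float
    N_sim: float
    sem_sim: float
    x_collapse: float


def one_step_phi(params: RunnerParams, theta: float) -> float:
    """Orientation change over one step after the periodic gait lands once
    on a uniform slope theta, evaluated numerically (no series truncation).

    Exactly one stance is simulated: the flat-gait landing state
    (v_x0, -v_y0, omega = 0) meets a contact whose tangent is inclined by
    theta, passes through the passive collision and the (terrain-fixed or
    laboratory-fixed) push-off, and the take-off state gives
    phi_step = 2 * v_y+ * omega+ (aerial time 2 v_y+ at angular rate
    omega+).  Zero on flat ground by construction of the push-off.
    """
    if not abs(theta) < math.pi / 2:
        raise ValueError("slope angle must satisfy |theta| < pi/2")
    if theta == 0.0:
        return 0.0
    pre = BodyState(
        x=0.0, y=1.0, phi=0.0, v_x=params.v_x0, v_y=-params.v_y0,
        omega=0.0, phase=Phase.PRE_COLLISION,
    )
    r_PG = np.array([math.sin(theta), -math.cos(theta)])
    contact = ContactEvent.from_slope(
        P=np.array([0.0, 1.0]) + r_PG, theta=theta, r_PG=r_PG
    )
    v_t, v_n = contact_point_velocity(pre, contact)
    if params.strategy is Strategy.OPEN_LOOP:
        v_t_target = params.eps_tc * params.v_x0
    else:
        v_t_target = params.eps_tc * v_t
    post_c = collision_with_targets(
        pre, contact, v_t_target, -params.eps_n * v_n, params.I_G
    )
    post = apply_pushoff(post_c, contact, pushoff_impulse(params), params.I_G)
    return 2.0 * post.v_y * post.omega


def phi_series(
    params: RunnerParams, theta: float, strategy=None, order: int = 2
) -> float:
    """Small-slope series of the one-step orientation change.

    order 1 keeps the linear term; order 2 adds the quadratic.  The
    open-loop linear coefficient 2 v_y0^2/(1+I_G) carries no collision
    parameter; the anticipatory series carries (1 - eps_tc) factors that
    vanish at perfect tangential-collision avoidance.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    strategy = Strategy(strategy) if strategy is not None else params.strategy
    I = params.I_G
    vx0, vy0, etc, en = params.v_x0, params.v_y0, params.eps_tc, params.eps_n

    if strategy is Strategy.OPEN_LOOP:
        c1 = 2.0 * vy0**2 / (1.0 + I)
        c2 = (
            (3.0 - I) / (1.0 + I) ** 2
            + 4.0 * I / (1.0 + I) ** 2 * etc
            + 2.0 / (1.0 + I) * en
        ) * vx0 * vy0
    else:
        c1 = 2.0 * vy0**2 / (1.0 + I) * (1.0 - etc)
        c2 = (
            (3.0 - I) / (1.0 + I) ** 2
            + (5.0 * I - 3.0) / (1.0 + I) ** 2 * etc
            - 4.0 * I / (1.0 + I) ** 2 * etc**2
            + 2.0 * (1.0 - etc) / (1.0 + I) * en
        ) * vx0 * vy0
    out = c1 * theta
    if order == 2:
        out += c2 * theta**2
    return out


def predict_steps(params: RunnerParams, theta: float):
    """Predicted mean steps to orientational failure and its eps_n
    sensitivity, from the small-I_G anticipatory series:

        N = phi_tol / [(1 - eps_tc) v_y0 theta (2 v_y0 + (3 + 2 eps_n) v_x0 theta)]

    Diverges (returned as inf) as eps_tc -> 1, where the orientation change
    vanishes and failures become translational instead.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    vx0, vy0, etc, en = params.v_x0, params.v_y0, params.eps_tc, params.eps_n
    denom = (1.0 - etc) * vy0 * theta * (2.0 * vy0 + (3.0 + 2.0 * en) * vx0 * theta)
    if denom <= 0.0:
        return math.inf, -math.inf
    N = params.phi_tol / denom
    dN_deps_n = -N / (2.0 * vy0 + (3.0 + 2.0 * en) * vx0 * theta) * 2.0 * vx0 * theta
    return N, dN_deps_n


def collapse_experiment(
    param_sets,
    terrain_spec: TerrainSpec = None,
    M: int = 1000,
    max_steps: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte Carlo mean steps to failure versus phi_tol/phi_step.

    For each parameter set, N_sim comes from an ensemble on the rough
    terrain and the collapse abscissa is phi_tol/phi_step with phi_step
    evaluated at the terrain's r.m.s. slope angle.  Parameter sets with
    eps_tc = 1 have phi_step = 0 (no orientational failures) and are
    excluded from the collapse.
    """
    if terrain_spec is None:
        terrain_spec = TerrainSpec()
    theta = rms_slope_angle(terrain_spec.dist, terrain_spec.lambda_)
    rows = []
    for i, p in enumerate(param_sets):
        phi_step = abs(one_step_phi(p, theta))
        if phi_step == 0.0:
            continue
        stats = run_ensemble(
            p, terrain_spec, M, max_steps=max_steps, seed=seed, key=(i,)
        )
        rows.append(
            ScalingRecord(
                params=p,
                theta=theta,
                phi_step=phi_step,
                N_pred=p.phi_tol / phi_step,
                N_sim=stats.mean_steps,
                sem_sim=stats.sem_steps,
                x_collapse=p.phi_tol / phi_step,
            )
        )
    return pd.DataFrame(
        {
            "I_G": [r.params.I_G for r in rows],
            "v_y0": [r.params.v_y0 for r in rows],
            "eps_n": [r.params.eps_n for r in rows],
            "eps_tc": [r.params.eps_tc for r in rows],
            "phi_tol": [r.params.phi_tol for r in rows],
            "theta": [r.theta for r in rows],
            "phi_step": [r.phi_step for r in rows],
            "x_collapse": [r.x_collapse for r in rows],
            "N_pred": [r.N_pred for r in rows],
            "N_sim": [r.N_sim for r in rows],
            "sem_sim": [r.sem_sim for r in rows],
        }
    )


def gravity_angular_impulse(touchdown_angle: float, params: RunnerParams):
    """Upper-bound estimate of the gravitational angular impulse about the
    contact point over a finite stance, and the orientation change it causes.

    An instantaneous stance ignores the moment of body weight about P.  For
    a finite stance at constant forward speed, the moment arm is the
    horizontal COM-to-P offset; a leg of unit length at touchdown angle
    beta bounds it by sin(beta).  The fully asymmetric admissible stance
    sweeps the arm from 0 to sin(beta) (a symmetric stance integrates to
    zero), giving

        |dH_P| <= sin(beta)^2 / (2 v_x0)

    and, integrating the induced angular rate (inertia about P is
    1 + I_G for a unit leg), a single-step orientation change

        |dphi| <= sin(beta)^3 / (6 v_x0^2 (1 + I_G)).
    """
    beta = float(touchdown_angle)
    if not 0.0 < beta < math.pi / 2:
        raise ValueError("touchdown angle must lie in (0, pi/2)")
    s = math.sin(beta)
    delta_H = s * s / (2.0 * params.v_x0)
    delta_phi = s**3 / (6.0 * params.v_x0**2 * (1.0 + params.I_G))
    return delta_H, delta_phi
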