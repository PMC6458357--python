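"""Rigid-disc stance mechanics for the impulsive running model.

The runner is a planar disc of mass ``m = 1``, leg length (disc radius)
``r_l = 1`` and moment of inertia ``I_G`` about its centre of mass, moving
under gravity ``g = 1``.  A step alternates ballistic flight with an
instantaneous stance.  Stance is a passive two-coefficient collision at the
contact point P, followed by an active push-off impulse that exactly restores
the periodic flat-ground gait (take-off velocity ``(v_x0, v_y0)``, zero spin).

Sign conventions (fixed here and relied upon by every other module): x is
forward, y is up, angles and angular velocity are counterclockwise positive,
the terrain tangent has positive x-component and the normal points away from
the ground (upward for sub-vertical slopes).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

__all__ = [
    "Strategy",
    "PushoffFrame",
    "Phase",
    "RunnerParams",
    "BodyState",
    "ContactEvent",
    "PushoffImpulse",
    "contact_point_velocity",
    "effective_eps_t",
    "passive_collision",
    "collision_with_targets",
    "pushoff_impulse",
    "apply_pushoff",
    "epsilon_hat",
    "kinetic_energy",
    "angular_momentum_about",
    "HUMAN_LIKE",
]


class Strategy(str, enum.Enum):
    """How the runner controls the tangential collision."""

    OPEN_LOOP = "open_loop"
    ANTICIPATORY = "anticipatory"


class PushoffFrame(str, enum.Enum):
    """Frame in which the invariant push-off impulse vector is expressed."""

    TERRAIN_FIXED = "terrain_fixed"
    LABORATORY_FIXED = "laboratory_fixed"


class Phase(str, enum.Enum):
    APEX = "apex"
    PRE_COLLISION = "pre_collision"
    POST_COLLISION = "post_collision"
    POST_PUSHOFF = "post_pushoff"


@dataclass(frozen=True)
class RunnerParams:
    """Inertial, collision, strategy and gait parameters (nondimensional).

    Defaults are the human-like runner: I_G = 0.17, eps_n = 0.63,
    phi_tol = pi/6, v_x0 = 0.96, v_y0 = 0.26.
    """

    I_G: float = 0.17
    eps_n: float = 0.63
    eps_tc: float = 0.0
    phi_tol: float = math.pi / 6
    v_x0: float = 0.96
    v_y0: float = 0.26
    strategy: Strategy = Strategy.OPEN_LOOP
    pushoff_frame: PushoffFrame = PushoffFrame.TERRAIN_FIXED
    delta_eps_t: float = 0.0
    v_stop: float = 0.01

    def __post_init__(self) -> None:
        if not self.I_G > 0:
            raise ValueError(f"I_G must be positive, got {self.I_G}")
        if not 0.0 <= self.eps_n <= 1.0:
            raise ValueError(f"eps_n must lie in [0, 1], got {self.eps_n}")
        if not 0.0 <= self.eps_tc <= 1.0:
            raise ValueError(f"eps_tc must lie in [0, 1], got {self.eps_tc}")
        if not self.v_x0 > 0:
            raise ValueError(f"v_x0 must be positive, got {self.v_x0}")
        if not self.v_y0 > 0:
            raise ValueError(f"v_y0 must be positive, got {self.v_y0}")
        if not self.phi_tol > 0:
            raise ValueError(f"phi_tol must be positive, got {self.phi_tol}")
        if not self.delta_eps_t >= 0:
            raise ValueError(f"delta_eps_t must be >= 0, got {self.delta_eps_t}")
        object.__setattr__(self, "strategy", Strategy(self.strategy))
        object.__setattr__(self, "pushoff_frame", PushoffFrame(self.pushoff_frame))

    def replace(self, **kw) -> "RunnerParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strategy"] = self.strategy.value
        d["pushoff_frame"] = self.pushoff_frame.value
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


#: Human-like reference runner (open-loop, terrain-fixed push-off).
HUMAN_LIKE = RunnerParams()


@dataclass
class BodyState:
    """Planar rigid-body state at a named phase of the step cycle."""

    x: float
    y: float
    phi: float
    v_x: float
    v_y: float
    omega: float
    phase: Phase = Phase.APEX

    def __post_init__(self) -> None:
        self.phase = Phase(self.phase)
        vals = (self.x, self.y, self.phi, self.v_x, self.v_y, self.omega)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite body state: {vals}")

    def copy(self, **kw) -> "BodyState":
        d = {**asdict(self), **kw}
        return BodyState(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase"] = self.phase.value
        return d


@dataclass
class ContactEvent:
    """Geometry and pre-collision kinematics at the new contact point P.

    ``r_PG`` points from the centre of mass G to P and has unit length (the
    disc radius is the leg length).  ``t_hat``/``n_hat`` are the local
    contact tangent (positive forward) and outward normal; the touchdown
    solver keeps ``n_hat`` anti-parallel to ``r_PG`` (radial across corner
    fans), which is what makes a unit tangential restitution spin-free.
    """

    P: np.ndarray
    t_hat: np.ndarray
    n_hat: np.ndarray
    theta: float
    r_PG: np.ndarray
    v_P_t: float = 0.0
    v_P_n: float = 0.0
    riser_contact: bool = False

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.t_hat = np.asarray(self.t_hat, dtype=float)
        self.n_hat = np.asarray(self.n_hat, dtype=float)
        self.r_PG = np.asarray(self.r_PG, dtype=float)
        if abs(np.linalg.norm(self.r_PG) - 1.0) > 1e-9:
            raise ValueError(
                f"|r_PG| must be 1 (unit leg length), got {np.linalg.norm(self.r_PG)}"
            )
        if abs(float(self.t_hat @ self.n_hat)) > 1e-12:
            raise ValueError("t_hat and n_hat must be orthogonal")

    @classmethod
    def from_slope(
        cls, P, theta: float, r_PG, riser_contact: bool = False
    ) -> "ContactEvent":
        t_hat = np.array([math.cos(theta), math.sin(theta)])
        n_hat = np.array([-math.sin(theta), math.cos(theta)])
        return cls(
            P=P, t_hat=t_hat, n_hat=n_hat, theta=theta, r_PG=r_PG,
            riser_contact=riser_contact,
        )

    def to_dict(self) -> dict:
        return {
            "P": self.P.tolist(),
            "t_hat": self.t_hat.tolist(),
            "n_hat": self.n_hat.tolist(),
            "theta": self.theta,
            "r_PG": self.r_PG.tolist(),
            "v_P_t": self.v_P_t,
            "v_P_n": self.v_P_n,
            "riser_contact": self.riser_contact,
        }


@dataclass(frozen=True)
class PushoffImpulse:
    """Linear impulse (J_t, J_n) in its frame and angular impulse J_phi at G.

    For the periodic flat-ground gait J_phi = 0; the impulse is computed once
    on flat ground and then held fixed on every terrain.
    """

    J_t: float
    J_n: float
    J_phi: float = 0.0
    frame: PushoffFrame = PushoffFrame.TERRAIN_FIXED

    def to_dict(self) -> dict:
        return {
            "J_t": self.J_t, "J_n": self.J_n, "J_phi": self.J_phi,
            "frame": PushoffFrame(self.frame).value,
        }


def _cross_z(a, b) -> float:
    """z-component of the planar cross product a x b."""
    return float(a[0] * b[1] - a[1] * b[0])


def kinetic_energy(state: BodyState, I_G: float) -> float:
    return 0.5 * (state.v_x**2 + state.v_y**2) + 0.5 * I_G * state.omega**2


def angular_momentum_about(state: BodyState, P, I_G: float) -> float:
    """Angular momentum about the fixed point P (m = 1): I_G*w + r_{G/P} x v_G."""
    r_GP = np.array([state.x, state.y]) - np.asarray(P, dtype=float)
    return I_G * state.omega + _cross_z(r_GP, [state.v_x, state.v_y])


def contact_point_velocity(state: BodyState, contact: ContactEvent):
    """Velocity of the material contact point resolved on (t_hat, n_hat).

    Rigid-body kinematics: v_P = v_G + omega * z_hat x r_{P/G}.
    """
    r = contact.r_PG
    if abs(np.linalg.norm(r) - 1.0) > 1e-9:
        raise ValueError("invalid contact geometry: |r_PG| != 1")
    v_P = np.array(
        [state.v_x - state.omega * r[1], state.v_y + state.omega * r[0]]
    )
    return float(v_P @ contact.t_hat), float(v_P @ contact.n_hat)


def effective_eps_t(params: RunnerParams, v_P_t_minus: float, rng=None) -> float:
    """Effective tangential restitution for this stance.

    Control noise (if ``delta_eps_t > 0``) perturbs the intended coefficient
    eps_tc by ``delta_eps_t * eta`` with eta ~ U[-1, 1] before the open-loop
    ratio is applied; the result may exceed 1.  The open-loop runner assumes
    the contact point approaches at the nominal speed v_x0, so its actual
    coefficient carries the ratio v_x0 / v_P,t^-.
    """
    eps = params.eps_tc
    if params.delta_eps_t > 0:
        if rng is None:
            raise ValueError("rng required when delta_eps_t > 0")
        eps = eps + params.delta_eps_t * rng.uniform(-1.0, 1.0)
    if params.strategy is Strategy.ANTICIPATORY:
        return float(eps)
    if v_P_t_minus == 0.0:
        raise ZeroDivisionError(
            "degenerate contact: open-loop eps_t undefined at v_P,t^- = 0"
        )
    return float(eps * params.v_x0 / v_P_t_minus)


def collision_with_targets(
    state_pre: BodyState,
    contact: ContactEvent,
    v_P_t_target: float,
    v_P_n_target: float,
    I_G: float,
) -> BodyState:
    """Solve the impulsive stance collision for prescribed post contact-point
    velocities.

    Three scalar constraints determine (v_x^c, v_y^c, omega^c): the two
    contact-point velocity targets and conservation of angular momentum about
    P (the collision impulse acts at P, so it has no moment about P).
    Position and orientation are unchanged (instantaneous stance).
    """
    r = contact.r_PG
    t, n = contact.t_hat, contact.n_hat
    # v_P(u) = (v_x - w r_y, v_y + w r_x) with u = (v_x, v_y, w)
    A = np.array(
        [
            [t[0], t[1], -t[0] * r[1] + t[1] * r[0]],
            [n[0], n[1], -n[0] * r[1] + n[1] * r[0]],
            # H_P = I_G w + (r_GP x v_G)_z with r_GP = -r
            [r[1], -r[0], I_G],
        ]
    )
    H_pre = I_G * state_pre.omega + (
        -r[0] * state_pre.v_y + r[1] * state_pre.v_x
    )
    b = np.array([v_P_t_target, v_P_n_target, H_pre])
    v_x_c, v_y_c, omega_c = np.linalg.solve(A, b)
    return state_pre.copy(
        v_x=float(v_x_c), v_y=float(v_y_c), omega=float(omega_c),
        phase=Phase.POST_COLLISION,
    )


def passive_collision(
    state_pre: BodyState,
    contact: ContactEvent,
    eps_t: float,
    eps_n: float,
    I_G: float,
) -> BodyState:
    """Passive two-coefficient collision at P.

    Post contact-point velocities are eps_t * v_P,t^- tangentially and
    -eps_n * v_P,n^- normally; angular momentum about P is conserved (the
    collision impulse acts at P and has no moment about it).
    """
    if state_pre.phase is not Phase.PRE_COLLISION:
        raise ValueError(f"expected pre_collision state, got {state_pre.phase}")
    v_t, v_n = contact_point_velocity(state_pre, contact)
    if v_n >= 0.0:
        raise ValueError(
            f"not a collision: contact normal velocity {v_n} >= 0 (separating)"
        )
    return collision_with_targets(state_pre, contact, eps_t * v_t, -eps_n * v_n, I_G)


def pushoff_impulse(params: RunnerParams) -> PushoffImpulse:
    """Flat-ground periodicity push-off impulse, applied at P after collision.

    Derived by requiring that the take-off state after a flat-ground stance
    with coefficients (eps_n, eps_tc) is exactly (v_x0, v_y0, omega = 0):

        J_t = I_G (1 - eps_tc) v_x0 / (1 + I_G),   J_n = (1 - eps_n) v_y0,

    and J_phi = 0 (the moment of J about G already cancels the collisional
    spin).  Held fixed step to step on every terrain.
    """
    J_t = params.I_G * (1.0 - params.eps_tc) * params.v_x0 / (1.0 + params.I_G)
    J_n = (1.0 - params.eps_n) * params.v_y0
    return PushoffImpulse(J_t=J_t, J_n=J_n, J_phi=0.0, frame=params.pushoff_frame)


def apply_pushoff(
    state_c: BodyState,
    contact: ContactEvent,
    imp: PushoffImpulse,
    I_G: float,
) -> BodyState:
    """Apply the active push-off impulse at P and the angular impulse at G.

    The linear impulse is rotated from its frame into laboratory axes:
    terrain-fixed means components on (t_hat, n_hat) of the current contact;
    laboratory-fixed means components on (x_hat, y_hat).  Angular update:
    I_G w+ = I_G w^c + (r_{P/G} x J)_z + J_phi.
    """
    if state_c.phase is not Phase.POST_COLLISION:
        raise ValueError(f"expected post_collision state, got {state_c.phase}")
    if PushoffFrame(imp.frame) is PushoffFrame.TERRAIN_FIXED:
        J = imp.J_t * contact.t_hat + imp.J_n * contact.n_hat
    else:
        J = np.array([imp.J_t, imp.J_n])
    r = contact.r_PG
    omega_p = state_c.omega + (_cross_z(r, J) + imp.J_phi) / I_G
    return state_c.copy(
        v_x=state_c.v_x + float(J[0]),
        v_y=state_c.v_y + float(J[1]),
        omega=float(omega_p),
        phase=Phase.POST_PUSHOFF,
    )


def epsilon_hat(v_x_pre: float, v_x_post_collision: float) -> float:
    """Observable proxy for the tangential restitution.

    eps_hat = 1 - dv_x / v_x, with dv_x the forward-momentum loss of the
    passive collision.  Equals eps_t exactly on flat terrain.
    """
    if v_x_pre <= 0.0:
        raise ValueError(f"epsilon_hat undefined for v_x_pre = {v_x_pre} <= 0")
    return 1.0 - (v_x_pre - v_x_post_collision) / v_x_pre
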