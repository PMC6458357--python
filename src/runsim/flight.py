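"""Ballistic flight, disc-terrain touchdown detection, and step composition.

The aerial phase is drag-free projectile motion in uniform gravity
(x'' = 0, y'' = -1, phi'' = 0).  Touchdown is the earliest time at which the
unit disc centred on the COM touches the terrain: either segment contact
(perpendicular distance from the COM to a segment equals 1 with the foot of
the perpendicular inside the segment) or corner contact (distance to a node
equals 1).  The root is bracketed by marching at a fraction of the grid
spacing and then polished by bisection on the signed clearance, which
guarantees the earliest contact even on terrain features much narrower than
a stride.

A full step composes: flight -> touchdown -> orientational failure check ->
passive collision -> push-off -> translational failure check -> flight to
the next apex.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model_core import (
    BodyState,
    ContactEvent,
    Phase,
    PushoffImpulse,
    RunnerParams,
    Strategy,
    apply_pushoff,
    collision_with_targets,
    contact_point_velocity,
    epsilon_hat,
    pushoff_impulse,
)
from .terrain import Terrain, TerrainKind

__all__ = [
    "FailureMode",
    "StepRecord",
    "clearance",
    "fly_to_touchdown",
    "initial_apex_state",
    "initial_takeoff_state",
    "run_trial",
    "support_height",
    "take_step",
]

#: Horizontal half-width of the candidate-element window around the COM.
_WINDOW = 1.05
#: Bisection bracket tolerance on the touchdown time.
_T_TOL = 1e-13
#: Penetration deepening (below take-off clearance) that counts as an
#: immediate touchdown when the disc never separates.
_C_DIP = 1e-4


class FailureMode(str, enum.Enum):
    NONE = "none"
    ORIENTATIONAL = "orientational"
    TRANSLATIONAL = "translational"


@dataclass
class StepRecord:
    """Per-step log of one apex-to-apex step."""

    step_index: int
    apex_state: BodyState
    contact: Optional[ContactEvent]
    eps_t_effective: float
    epsilon_hat: float
    post_state: Optional[BodyState]
    failure: FailureMode
    phi_at_touchdown: float
    next_apex: Optional[BodyState] = None


def _candidate_elements(terrain: Terrain, x: float):
    """Segment endpoints (p0, p1) of contactable elements near x.

    Rough terrains expose the interpolating polyline; step-like terrains
    expose only the horizontal treads (risers are excluded contact zones).
    """
    nodes, heights = terrain.nodes, terrain.heights
    i0 = max(0, int(np.searchsorted(nodes, x - _WINDOW)) - 1)
    i1 = min(nodes.size - 1, int(np.searchsorted(nodes, x + _WINDOW)) + 1)
    if i1 <= i0:
        i1 = i0 + 1
    if terrain.kind is TerrainKind.STEP_LIKE:
        xs0 = nodes[i0:i1]
        xs1 = nodes[i0 + 1 : i1 + 1]
        hs = heights[i0:i1]
        p0 = np.stack([xs0, hs], axis=1)
        p1 = np.stack([xs1, hs], axis=1)
    else:
        p0 = np.stack([nodes[i0:i1], heights[i0:i1]], axis=1)
        p1 = np.stack([nodes[i0 + 1 : i1 + 1], heights[i0 + 1 : i1 + 1]], axis=1)
    return p0, p1


def _closest_point(terrain: Terrain, G: np.ndarray):
    """Closest point on the contactable terrain elements to G.

    Returns (distance, P, on_interior) where on_interior is True for a foot
    of perpendicular strictly inside a segment (False: node/corner).
    """
    p0, p1 = _candidate_elements(terrain, float(G[0]))
    d = p1 - p0
    L2 = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,ij->i", G[None, :] - p0, d) / L2, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    dist = np.hypot(*(G[None, :] - proj).T)
    k = int(np.argmin(dist))
    eps = 1e-12
    on_interior = eps < t[k] < 1.0 - eps
    return float(dist[k]), proj[k], on_interior


def clearance(terrain: Terrain, G) -> float:
    """Signed clearance of the unit disc centred at G: distance - 1."""
    dist, _, _ = _closest_point(terrain, np.asarray(G, dtype=float))
    return dist - 1.0


def _flight_position(state: BodyState, t: float) -> np.ndarray:
    return np.array(
        [state.x + state.v_x * t, state.y + state.v_y * t - 0.5 * t * t]
    )


def fly_to_touchdown(
    state_takeoff: BodyState, terrain: Terrain
) -> tuple:
    """Propagate the ballistic flight to the earliest disc-terrain contact.

    Returns (pre-collision BodyState, ContactEvent).  Raises if the take-off
    state already penetrates the terrain or if no touchdown is found within
    the ballistic horizon.
    """
    s = state_takeoff
    c0 = clearance(terrain, (s.x, s.y))
    # A take-off state sits essentially at contact (clearance ~ 0); a small
    # negative value can occur after a corner push-off whose smoothed normal
    # differs slightly from the radial direction.
    if c0 < -5e-3:
        raise ValueError(f"invalid take-off: disc penetrates terrain by {-c0}")

    lam = terrain.lambda_ if terrain.nodes.size > 2 else 0.1
    dt = lam / (4.0 * max(abs(s.v_x), 0.25))
    # ballistic horizon: time to fall 2 units below the lowest terrain node
    y_min = float(np.min(terrain.heights)) - 2.0
    disc = s.v_y * s.v_y + 2.0 * (s.y - y_min)
    t_max = s.v_y + math.sqrt(max(disc, 0.0))

    # Touchdown is sought on the descending branch of the flight parabola
    # (from the apex onward); grazes against rising ground during the ascent
    # are not stance events.  The search starts at the apex, or at take-off
    # when the take-off vertical velocity is already non-positive.
    t0 = max(s.v_y, 0.0)
    c_start = clearance(terrain, _flight_position(s, t0))
    if t0 > 0.0 and c_start < 0.0:
        # still overlapping rising ground at the apex: stance begins there
        t_td = t0
    else:
        # when starting exactly at a departing contact (t0 = 0, c ~ 0), arm
        # detection only once the disc has separated, or accept penetration
        # deepening beyond _C_DIP as an immediate touchdown
        armed = c_start > 1e-9
        thr_immediate = min(c_start, 0.0) - _C_DIP
        t_prev, c_prev = t0, c_start
        t = t0 + dt
        bracket = None
        threshold = 0.0
        while t <= t_max + dt:
            c = clearance(terrain, _flight_position(s, t))
            if not armed:
                if c > 1e-9:
                    armed = True
                elif c < thr_immediate:
                    bracket = (t_prev, t)
                    threshold = thr_immediate
                    break
            elif c < 0.0 and c_prev >= 0.0:
                bracket = (t_prev, t)
                break
            t_prev, c_prev = t, c
            t += dt
        if bracket is None:
            raise RuntimeError(
                "no touchdown within ballistic horizon (runner left the terrain?)"
            )
        lo, hi = bracket
        while hi - lo > _T_TOL:
            mid = 0.5 * (lo + hi)
            if clearance(terrain, _flight_position(s, mid)) < threshold:
                hi = mid
            else:
                lo = mid
        t_td = 0.5 * (lo + hi)

    G = _flight_position(s, t_td)
    dist, P, on_interior = _closest_point(terrain, G)
    # The leg points from G to the contact point, and the contact normal is
    # taken anti-parallel to it: perpendicular to the segment for interior
    # contacts, radial (the rounded-corner normal fan) for node contacts.
    # Keeping n_hat || -r_PG is what makes an eps_t = 1 collision spin-free
    # on any local geometry.  The effective slope is the tangent angle.
    riser = False
    if terrain.kind is TerrainKind.STEP_LIKE:
        # step-like terrains have only height variations: the contact tangent
        # comes from the (flat) landing tread, so the stance is always level.
        # A leading tread edge whose level is clearly above the disc bottom
        # is a riser-face strike (the step exceeded the jump clearance).
        riser = (
            (not on_interior)
            and P[0] > G[0]
            and (P[1] - (G[1] - 1.0)) > 0.02
        )
        theta = 0.0
        r_PG = np.array([0.0, -1.0])
        P = G + r_PG
    else:
        r_PG = (P - G) / dist
        theta = math.atan2(r_PG[0], -r_PG[1])  # angle of t_hat (perp to n_hat)
    contact = ContactEvent.from_slope(P=P, theta=theta, r_PG=r_PG, riser_contact=riser)

    pre = s.copy(
        x=float(G[0]),
        y=float(G[1]),
        phi=s.phi + s.omega * t_td,
        v_y=s.v_y - t_td,
        phase=Phase.PRE_COLLISION,
    )
    v_t, v_n = contact_point_velocity(pre, contact)
    contact.v_P_t, contact.v_P_n = v_t, v_n
    return pre, contact


def _fly_to_apex(state: BodyState) -> BodyState:
    """Analytic flight from take-off to the next apex (v_y = 0)."""
    t = max(state.v_y, 0.0)
    return state.copy(
        x=state.x + state.v_x * t,
        y=state.y + state.v_y * t - 0.5 * t * t,
        phi=state.phi + state.omega * t,
        v_y=0.0,
        phase=Phase.APEX,
    )


def support_height(terrain: Terrain, x0: float) -> float:
    """COM height at which the unit disc exactly rests on the terrain at x0.

    Monotone in y, solved by bisection; on flat ground this is h(x0) + 1.
    """
    lo = float(terrain.height(x0)) + 1.0
    hi = float(np.max(terrain.heights)) + 1.5
    if clearance(terrain, (x0, lo)) >= 0.0:
        return lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if clearance(terrain, (x0, mid)) < 0.0:
            lo = mid
        else:
            hi = mid
    return hi


def initial_takeoff_state(
    params: RunnerParams, terrain: Terrain, x0: float = 0.0
) -> BodyState:
    """Take-off state with the disc resting on the terrain at x0, nominal
    gait velocities, upright and spin-free."""
    y0 = support_height(terrain, x0)
    return BodyState(
        x=x0, y=y0, phi=0.0, v_x=params.v_x0, v_y=params.v_y0,
        omega=0.0, phase=Phase.POST_PUSHOFF,
    )


def initial_apex_state(params: RunnerParams, terrain: Terrain, x0: float = 0.0) -> BodyState:
    """Apex state following the initial take-off (see initial_takeoff_state).

    Note: on rough terrain the disc may contact a bump before reaching this
    formal apex; trial stepping therefore iterates take-off states.
    """
    return _fly_to_apex(initial_takeoff_state(params, terrain, x0))


def take_step(
    state_apex: BodyState,
    terrain: Terrain,
    params: RunnerParams,
    imp: PushoffImpulse,
    rng: Optional[np.random.Generator] = None,
    step_index: int = 0,
) -> StepRecord:
    """One full apex-to-apex step, with failure checks.

    Orientational failure (|phi| > phi_tol) is checked at touchdown only;
    translational failure (v_x < v_stop) immediately after push-off.  The
    returned record is terminal when a failure occurred.

    The step may start from an apex state or directly from a take-off
    (post-push-off) state; the latter also catches contacts that occur while
    the disc is still ascending, which matters when bump heights are
    comparable to the apex clearance.
    """
    if state_apex.phase not in (Phase.APEX, Phase.POST_PUSHOFF):
        raise ValueError(
            f"take_step requires an apex or take-off state, got {state_apex.phase}"
        )
    # formal apex of the incoming flight, for logging (touchdown may precede it)
    apex_log = (
        _fly_to_apex(state_apex)
        if state_apex.phase is Phase.POST_PUSHOFF
        else state_apex
    )

    pre, contact = fly_to_touchdown(state_apex, terrain)
    if abs(pre.phi) > params.phi_tol:
        return StepRecord(
            step_index=step_index, apex_state=apex_log, contact=contact,
            eps_t_effective=math.nan, epsilon_hat=math.nan, post_state=None,
            failure=FailureMode.ORIENTATIONAL, phi_at_touchdown=pre.phi,
        )

    # Effective tangential control.  The open-loop runner aims for the
    # contact-point speed it would see on flat ground at the nominal gait
    # (v_P,t^- = v_x0), so its target post-collision tangential velocity is
    # eps_tc_eff * v_x0 regardless of the actual approach speed; this is the
    # finite form of eps_t = eps_tc * v_x0 / v_P,t^-.
    eps_tc_eff = params.eps_tc
    if params.delta_eps_t > 0:
        if rng is None:
            raise ValueError("rng required when delta_eps_t > 0")
        eps_tc_eff = eps_tc_eff + params.delta_eps_t * rng.uniform(-1.0, 1.0)
    v_t_minus, v_n_minus = contact.v_P_t, contact.v_P_n
    if params.strategy is Strategy.OPEN_LOOP:
        v_t_target = eps_tc_eff * params.v_x0
        eps_t = v_t_target / v_t_minus if v_t_minus != 0.0 else math.inf
    else:
        eps_t = eps_tc_eff
        v_t_target = eps_t * v_t_minus
    # Grazing touchdown: at a corner the smoothed-slope normal differs from
    # the radial direction and spin moves the material point, so v_P,n^- can
    # be >= 0 at geometric contact.  No normal impulse is needed then; the
    # normal component is left unchanged (continuous limit of -eps_n*v_n as
    # v_n -> 0^-), while tangential control still applies.
    v_n_target = -params.eps_n * v_n_minus if v_n_minus < 0.0 else v_n_minus
    post_c = collision_with_targets(
        pre, contact, v_t_target, v_n_target, params.I_G
    )
    eps_hat = epsilon_hat(pre.v_x, post_c.v_x)

    post = apply_pushoff(post_c, contact, imp, params.I_G)
    # Project any residual geometric penetration out along the clearance
    # gradient (the smoothed-slope contact plane and the polyline differ by
    # O(1e-4) near corners; without this the error would ratchet over
    # repeated grazing contacts on a climb).
    for _ in range(3):
        c_post = clearance(terrain, (post.x, post.y))
        if c_post >= -1e-12:
            break
        dist_g, P_g, _ = _closest_point(terrain, np.array([post.x, post.y]))
        g_hat = (np.array([post.x, post.y]) - P_g) / dist_g
        post = post.copy(
            x=post.x - c_post * float(g_hat[0]),
            y=post.y - c_post * float(g_hat[1]),
        )
    if post.v_x < params.v_stop:
        return StepRecord(
            step_index=step_index, apex_state=apex_log, contact=contact,
            eps_t_effective=eps_t, epsilon_hat=eps_hat, post_state=post,
            failure=FailureMode.TRANSLATIONAL, phi_at_touchdown=pre.phi,
        )

    apex_next = _fly_to_apex(post)
    return StepRecord(
        step_index=step_index, apex_state=apex_log, contact=contact,
        eps_t_effective=eps_t, epsilon_hat=eps_hat, post_state=post,
        failure=FailureMode.NONE, phi_at_touchdown=pre.phi,
        next_apex=apex_next,
    )


def run_trial(
    params: RunnerParams,
    terrain: Terrain,
    max_steps: int,
    rng: Optional[np.random.Generator] = None,
    collect_trace: bool = True,
):
    """Run one trial until failure or max_steps completed steps.

    Steps-to-failure counts successfully completed steps before the failure
    event (a runner failing at its first touchdown scores 0).  Returns
    (steps_to_failure, FailureMode, trace list of StepRecord).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    imp = pushoff_impulse(params)
    state = initial_takeoff_state(params, terrain)
    trace = []
    for k in range(1, max_steps + 1):
        rec = take_step(state, terrain, params, imp, rng=rng, step_index=k)
        if collect_trace:
            trace.append(rec)
        if rec.failure is not FailureMode.NONE:
            return k - 1, rec.failure, trace
        state = rec.post_state
    return max_steps, FailureMode.NONE, trace
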