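"""Numba-compiled per-trial stepping kernel for Monte Carlo ensembles.

Mirrors the reference implementation in ``runsim.flight`` operation for
operation (same touchdown bracketing and bisection constants, same contact
geometry, same collision closed form with the leg along the contact normal,
same push-off and penetration projection).  Single-step agreement with the
reference path is asserted in the test suite; whole trajectories can still
part ways after many tens of steps through chaotic amplification of
last-ulp libm differences, which is statistically irrelevant.

Trial outcome codes: 0 = censored at max_steps, 1 = orientational failure,
2 = translational failure, 3 = ran past the generated terrain (caller
should retry with a longer terrain), 4 = no touchdown found.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_WINDOW = 1.05
_T_TOL = 1e-13
_C_DIP = 1e-4

OUTCOME_CENSORED = 0
OUTCOME_ORIENTATIONAL = 1
OUTCOME_TRANSLATIONAL = 2
OUTCOME_RAN_OFF_TERRAIN = 3
OUTCOME_NO_TOUCHDOWN = 4


@njit(cache=True)
def _closest(heights, x0, lam, step_like, gx, gy):
    """Distance, closest point and interior flag for the contactable
    elements (polyline segments, or horizontal treads when step_like)."""
    n = heights.shape[0]
    i0 = int(np.floor((gx - _WINDOW - x0) / lam)) - 1
    i1 = int(np.ceil((gx + _WINDOW - x0) / lam)) + 1
    if i0 < 0:
        i0 = 0
    if i1 > n - 2:
        i1 = n - 2
    best_d2 = 1e300
    best_px = 0.0
    best_py = 0.0
    best_t = 0.0
    for i in range(i0, i1 + 1):
        x1 = x0 + i * lam
        y1 = heights[i]
        if step_like:
            dy = 0.0
        else:
            dy = heights[i + 1] - y1
        L2 = lam * lam + dy * dy
        t = ((gx - x1) * lam + (gy - y1) * dy) / L2
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
        px = x1 + t * lam
        py = y1 + t * dy
        d2 = (gx - px) * (gx - px) + (gy - py) * (gy - py)
        if d2 < best_d2:
            best_d2 = d2
            best_px = px
            best_py = py
            best_t = t
    interior = 1e-12 < best_t < 1.0 - 1e-12
    return np.sqrt(best_d2), best_px, best_py, interior


@njit(cache=True)
def _clearance(heights, x0, lam, step_like, gx, gy):
    d, _, _, _ = _closest(heights, x0, lam, step_like, gx, gy)
    return d - 1.0


@njit(cache=True)
def _height_at(heights, x0, lam, step_like, x):
    n = heights.shape[0]
    i = int(np.floor((x - x0) / lam))
    if i < 0:
        i = 0
    if i > n - 2:
        i = n - 2
    if step_like:
        return heights[i]
    t = (x - (x0 + i * lam)) / lam
    return heights[i] * (1.0 - t) + heights[i + 1] * t


@njit(cache=True)
def _support_height(heights, x0, lam, step_like, x):
    lo = _height_at(heights, x0, lam, step_like, x) + 1.0
    if _clearance(heights, x0, lam, step_like, x, lo) >= 0.0:
        return lo
    hi = np.max(heights) + 1.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _clearance(heights, x0, lam, step_like, x, mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return hi


@njit(cache=True)
def run_trial_kernel(
    heights,
    x0,
    lam,
    step_like,
    I_G,
    eps_n,
    eps_tc,
    phi_tol,
    v_x0,
    v_y0,
    open_loop,
    delta_eps_t,
    v_stop,
    lab_frame,
    etas,
    max_steps,
    eps_hat_out,
    theta_out,
):
    """Run one trial; returns (steps_to_failure, outcome code).

    ``etas`` holds one pre-drawn U[-1, 1] noise variate per step;
    ``eps_hat_out``/``theta_out`` (length >= max_steps) receive the per-step
    forward-momentum observable and contact slope (NaN where undefined).
    """
    n = heights.shape[0]
    x_end = x0 + (n - 1) * lam
    J_t = I_G * (1.0 - eps_tc) * v_x0 / (1.0 + I_G)
    J_n = (1.0 - eps_n) * v_y0

    gx = 0.0
    gy = _support_height(heights, x0, lam, step_like, 0.0)
    phi = 0.0
    vx = v_x0
    vy = v_y0
    omega = 0.0

    for k in range(1, max_steps + 1):
        eps_hat_out[k - 1] = np.nan
        theta_out[k - 1] = np.nan
        if gx > x_end - 2.0:
            return k - 1, OUTCOME_RAN_OFF_TERRAIN

        # --- flight to touchdown (descending branch) ---
        c0 = _clearance(heights, x0, lam, step_like, gx, gy)
        dt = lam / (4.0 * max(abs(vx), 0.25))
        y_min = np.min(heights) - 2.0
        disc = vy * vy + 2.0 * (gy - y_min)
        if disc < 0.0:
            disc = 0.0
        t_max = vy + np.sqrt(disc)

        t0 = vy if vy > 0.0 else 0.0
        cx = gx + vx * t0
        cy = gy + vy * t0 - 0.5 * t0 * t0
        c_start = _clearance(heights, x0, lam, step_like, cx, cy)
        t_td = -1.0
        if t0 > 0.0 and c_start < 0.0:
            t_td = t0
        else:
            armed = c_start > 1e-9
            thr_imm = (c_start if c_start < 0.0 else 0.0) - _C_DIP
            t_prev = t0
            c_prev = c_start
            t = t0 + dt
            lo = -1.0
            hi = -1.0
            threshold = 0.0
            while t <= t_max + dt:
                px = gx + vx * t
                py = gy + vy * t - 0.5 * t * t
                c = _clearance(heights, x0, lam, step_like, px, py)
                if not armed:
                    if c > 1e-9:
                        armed = True
                    elif c < thr_imm:
                        lo = t_prev
                        hi = t
                        threshold = thr_imm
                        break
                elif c < 0.0 and c_prev >= 0.0:
                    lo = t_prev
                    hi = t
                    break
                t_prev = t
                c_prev = c
                t += dt
            if lo < 0.0:
                return k - 1, OUTCOME_NO_TOUCHDOWN
            while hi - lo > _T_TOL:
                mid = 0.5 * (lo + hi)
                px = gx + vx * mid
                py = gy + vy * mid - 0.5 * mid * mid
                if _clearance(heights, x0, lam, step_like, px, py) < threshold:
                    hi = mid
                else:
                    lo = mid
            t_td = 0.5 * (lo + hi)

        gx = gx + vx * t_td
        gy = gy + vy * t_td - 0.5 * t_td * t_td
        phi = phi + omega * t_td
        vy = vy - t_td

        if abs(phi) > phi_tol:
            return k - 1, OUTCOME_ORIENTATIONAL

        # --- contact geometry: leg along the contact normal ---
        dist, px, py, interior = _closest(heights, x0, lam, step_like, gx, gy)
        if step_like:
            theta = 0.0
            rx = 0.0
            ry = -1.0
        else:
            rx = (px - gx) / dist
            ry = (py - gy) / dist
            theta = np.arctan2(rx, -ry)
        theta_out[k - 1] = theta
        ct = np.cos(theta)
        st = np.sin(theta)

        # tangential/normal split (t_hat = (ct, st), n_hat = (-st, ct))
        vt = vx * ct + vy * st
        vn = -vx * st + vy * ct
        v_P_t = vt + omega  # r = -n_hat: z_hat x r = t_hat
        v_P_n = vn

        eps_eff = eps_tc
        if delta_eps_t > 0.0:
            eps_eff = eps_tc + delta_eps_t * etas[k - 1]
        if open_loop:
            v_P_t_target = eps_eff * v_x0
        else:
            v_P_t_target = eps_eff * v_P_t
        v_P_n_target = -eps_n * v_P_n if v_P_n < 0.0 else v_P_n

        # collision: v_t^c + w^c = target_t ; v_n^c = target_n ;
        # I w^c - v_t^c = I w - v_t  (angular momentum about P)
        omega_c = (I_G * omega - vt + v_P_t_target) / (1.0 + I_G)
        vt_c = v_P_t_target - omega_c
        vn_c = v_P_n_target
        vx_c = vt_c * ct - vn_c * st
        eps_hat_out[k - 1] = 1.0 - (vx - vx_c) / vx

        # --- push-off ---
        if lab_frame:
            Jx = J_t
            Jy = J_n
        else:
            Jx = J_t * ct - J_n * st
            Jy = J_t * st + J_n * ct
        rxJ = rx * Jy - ry * Jx
        omega = omega_c + rxJ / I_G
        vx = vx_c + Jx
        vy = vt_c * st + vn_c * ct + Jy

        # --- project residual penetration out along the clearance gradient
        for _ in range(3):
            c_post = _clearance(heights, x0, lam, step_like, gx, gy)
            if c_post >= -1e-12:
                break
            d_g, pgx, pgy, _ = _closest(heights, x0, lam, step_like, gx, gy)
            gx = gx - c_post * (gx - pgx) / d_g
            gy = gy - c_post * (gy - pgy) / d_g

        if vx < v_stop:
            return k - 1, OUTCOME_TRANSLATIONAL

    return max_steps, OUTCOME_CENSORED
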