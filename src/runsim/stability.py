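"""Linear stability of the periodic flat-ground gait.

The apex-to-apex Poincare return map is taken at the apex of the aerial
phase (v_y = 0), with the state psi = (x, y, phi, v_x, omega) measured in a
Newtonian frame translating forward at the nominal speed v_x0, so the
periodic gait is the fixed point psi* = 0.  The map is linearized by central
finite differences; the resulting 5x5 Floquet matrix T has a defective
(non-diagonalizable) unity eigenvalue whose Jordan structure - not a
magnitude-greater-than-one eigenvalue - is what makes the runner unstable:
perturbations along a generalized eigenvector grow linearly with the number
of steps.

For eps_tc < 1 the unity eigenvalue has algebraic multiplicity 3 and
geometric multiplicity 2 (eigenvectors along pure orientation and pure
translation shifts); at eps_tc = 1 a fourth unity eigenvalue joins (forward
speed decouples from spin) while still only two eigenvectors exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .flight import fly_to_touchdown, take_step, FailureMode
from .model_core import (
    BodyState,
    Phase,
    RunnerParams,
    pushoff_impulse,
)
from .terrain import flat_terrain

__all__ = [
    "LinearizedMap",
    "return_map_flat",
    "linearize_return_map",
    "jordan_structure",
    "perturbation_growth",
]


@dataclass
class LinearizedMap:
    """Linearization of the apex return map at the periodic gait.

    State ordering: psi = (x, y, phi, v_x, omega).
    """

    T: np.ndarray
    eigenvalues: np.ndarray
    alg_mult_unity: int
    geo_mult_unity: int
    basis: list                     # Jordan chains of the unity eigenvalue
    fd_step: float
    params: RunnerParams = None

    def to_dict(self) -> dict:
        return {
            "T": self.T.tolist(),
            "eigenvalues_real": np.real(self.eigenvalues).tolist(),
            "eigenvalues_imag": np.imag(self.eigenvalues).tolist(),
            "alg_mult_unity": self.alg_mult_unity,
            "geo_mult_unity": self.geo_mult_unity,
            "basis": [[v.tolist() for v in chain] for chain in self.basis],
            "fd_step": self.fd_step,
            "params": self.params.to_dict() if self.params else None,
        }


def return_map_flat(psi, params: RunnerParams) -> np.ndarray:
    """One application of the apex-to-apex return map on flat ground.

    ``psi = (x, y, phi, v_x, omega)`` are deviations from the periodic
    gait's apex state, with x and v_x measured in the frame translating at
    v_x0.  psi = 0 maps to 0 by construction of the push-off impulse.
    """
    psi = np.asarray(psi, dtype=float)
    terrain = flat_terrain(extent=200.0, x_start=-50.0)
    imp = pushoff_impulse(params)
    y_apex = 1.0 + 0.5 * params.v_y0**2

    apex = BodyState(
        x=float(psi[0]),
        y=y_apex + float(psi[1]),
        phi=float(psi[2]),
        v_x=params.v_x0 + float(psi[3]),
        v_y=0.0,
        omega=float(psi[4]),
        phase=Phase.APEX,
    )
    pre, _contact = fly_to_touchdown(apex, terrain)
    t_down = apex.v_y - pre.v_y  # fall time (v_y decreases at unit rate)
    rec = take_step(apex, terrain, params, imp)
    if rec.failure is not FailureMode.NONE:
        raise ValueError(f"perturbation leaves the gait's domain: {rec.failure}")
    nxt = rec.next_apex
    t_up = rec.post_state.v_y
    T_step = t_down + t_up
    return np.array(
        [
            nxt.x - params.v_x0 * T_step,
            nxt.y - y_apex,
            nxt.phi,
            nxt.v_x - params.v_x0,
            nxt.omega,
        ]
    )


def linearize_return_map(
    params: RunnerParams, fd_step: float = 1e-6, tol: float = None
) -> LinearizedMap:
    """Central-difference Jacobian of the flat-ground return map at psi* = 0.

    A Richardson consistency check at fd_step/2 must agree entrywise to
    1e-6; failure indicates the map is not smooth at the requested point.
    """
    if fd_step <= 0:
        raise ValueError("fd_step must be positive")

    def jac(h: float) -> np.ndarray:
        J = np.empty((5, 5))
        for j in range(5):
            e = np.zeros(5)
            e[j] = h
            J[:, j] = (return_map_flat(e, params) - return_map_flat(-e, params)) / (
                2.0 * h
            )
        return J

    T = jac(fd_step)
    T_half = jac(fd_step / 2.0)
    err = np.max(np.abs(T - T_half))
    if err > 1e-6:
        bad = np.argwhere(np.abs(T - T_half) > 1e-6)
        raise ArithmeticError(
            f"finite-difference Jacobian inconsistent under step halving "
            f"(max deviation {err:.2e} at entries {bad.tolist()})"
        )
    T = T_half  # the finer estimate

    if tol is None:
        # rank threshold must sit above the finite-difference noise floor:
        # the touchdown solve is exact to ~1e-13 in the state, so Jacobian
        # entries carry ~1e-13/fd_step of roundoff
        tol = max(1e-8 * np.linalg.norm(T, 2), 50.0 * 1e-13 / fd_step)
    eigenvalues, alg, geo, chains = jordan_structure(T, tol=tol)
    return LinearizedMap(
        T=T, eigenvalues=eigenvalues, alg_mult_unity=alg, geo_mult_unity=geo,
        basis=chains, fd_step=fd_step, params=params,
    )


def jordan_structure(T: np.ndarray, tol: float = None):
    """Multiplicities and Jordan chains of the unity eigenvalue of T.

    The algebraic/geometric multiplicities follow from the ranks of
    (T - I)^k: the number of Jordan blocks of size >= k equals
    rank((T-I)^(k-1)) - rank((T-I)^k).  Ranks use a singular-value
    threshold ``tol`` (default 1e-8 * ||T||_2).
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    if tol is None:
        tol = 1e-8 * np.linalg.norm(T, 2)
    if tol <= 0:
        raise ValueError("tol must be positive")

    eigenvalues = np.linalg.eigvals(T)

    A = T - np.eye(n)
    ranks = [n]
    Ak = np.eye(n)
    for _ in range(n):
        Ak = Ak @ A
        ranks.append(int(np.sum(np.linalg.svd(Ak, compute_uv=False) > tol)))

    blocks_ge = [ranks[k - 1] - ranks[k] for k in range(1, n + 1)]
    if any(b < 0 for b in blocks_ge) or any(
        blocks_ge[i] < blocks_ge[i + 1] for i in range(len(blocks_ge) - 1)
    ):
        raise ArithmeticError(
            f"rank sequence {ranks} inconsistent with a Jordan structure at "
            f"tol={tol:.2e}; adjust tol"
        )
    geo = blocks_ge[0]
    alg = n - ranks[-1]

    # Jordan chains: seed each block with a vector in null((T-I)^k) that is
    # outside null((T-I)^(k-1)) + previously used chains, then iterate A.
    def null_basis(k: int) -> np.ndarray:
        if k == 0:
            return np.zeros((n, 0))
        M = np.linalg.matrix_power(A, k)
        _u, s, vh = np.linalg.svd(M)
        rank = int(np.sum(s > tol))
        return vh[rank:].T  # orthonormal null-space basis

    chains = []
    used = np.zeros((n, 0))
    block_sizes = []
    for k in range(n, 0, -1):
        for _ in range(blocks_ge[k - 1] - (blocks_ge[k] if k < n else 0)):
            block_sizes.append(k)
    for k in block_sizes:
        Nk = null_basis(k)
        lower = np.hstack([null_basis(k - 1), used])
        # component of Nk outside span(lower)
        if lower.shape[1]:
            q, _ = np.linalg.qr(lower)
            proj = Nk - q @ (q.T @ Nk)
        else:
            proj = Nk
        norms = np.linalg.norm(proj, axis=0)
        j = int(np.argmax(norms))
        if norms[j] < math.sqrt(tol):
            raise ArithmeticError("failed to extract a Jordan chain seed")
        top = proj[:, j] / norms[j]
        chain = [top]
        for _ in range(k - 1):
            chain.append(A @ chain[-1])
        chain.reverse()  # eigenvector first
        chains.append(chain)
        used = np.hstack([used] + [c.reshape(-1, 1) for c in chain])

    return eigenvalues, alg, geo, chains


def perturbation_growth(lin: LinearizedMap, dpsi0, n: int) -> np.ndarray:
    """T^n applied to an initial perturbation.

    Along a generalized eigenvector of the unity eigenvalue the growth is
    exactly linear in the number of steps:
    T^n dpsi = dpsi + n (T - I) dpsi.
    """
    v = np.asarray(dpsi0, dtype=float)
    return np.linalg.matrix_power(lin.T, n) @ v
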