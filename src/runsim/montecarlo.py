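"""Monte Carlo ensembles: steps-to-failure statistics and parameter sweeps.

Each trial draws a fresh, independent terrain realization and (when control
noise is on) its own noise stream, both spawned deterministically from the
global seed and the trial index, so results are independent of execution
order or batching.  Censored trials (reaching ``max_steps``) are excluded
from the mean/sd of steps-to-failure and reported separately; with the
human-like parameter set on the reference terrain no trial survives that
long.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .model_core import PushoffFrame, RunnerParams, Strategy
from .terrain import TerrainKind, TerrainSpec

__all__ = [
    "EnsembleStats",
    "run_ensemble",
    "sweep_grid",
    "eps_hat_statistics",
]

#: number of leading steps for which per-step eps-hat summaries are kept
_EPS_HAT_STEPS = 50

_MODE_NAMES = {
    _kernels.OUTCOME_CENSORED: "none",
    _kernels.OUTCOME_ORIENTATIONAL: "orientational",
    _kernels.OUTCOME_TRANSLATIONAL: "translational",
}


@dataclass
class EnsembleStats:
    """Aggregate failure statistics of a Monte Carlo ensemble."""

    M: int
    max_steps: int
    seed: int
    params: RunnerParams
    terrain: TerrainSpec
    mean_steps: float
    sd_steps: float
    failure_mode_fractions: dict
    survival_curve: np.ndarray          # P(steps >= n) at n = 0..max observed
    steps_histogram: np.ndarray         # counts at steps = 0..max observed
    eps_hat_by_step: pd.DataFrame       # step, mean, sd, n (surviving trials)
    steps: np.ndarray = field(repr=False, default=None)
    modes: np.ndarray = field(repr=False, default=None)

    @property
    def sem_steps(self) -> float:
        n_failed = int(np.sum(self.modes != _kernels.OUTCOME_CENSORED))
        return self.sd_steps / math.sqrt(max(n_failed, 1))

    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "max_steps": self.max_steps,
            "seed": self.seed,
            "params": self.params.to_dict(),
            "terrain": self.terrain.to_dict(),
            "mean_steps": self.mean_steps,
            "sd_steps": self.sd_steps,
            "failure_mode_fractions": self.failure_mode_fractions,
            "survival_curve": self.survival_curve.tolist(),
            "steps_histogram": self.steps_histogram.tolist(),
        }


def _trial_extent(params: RunnerParams, max_steps: int) -> float:
    # nominal stride 2*v_x0*v_y0 with a generous safety factor; trials that
    # still outrun the terrain are retried on a doubled extent
    stride = max(2.0 * params.v_x0 * params.v_y0, 0.4)
    return 2.5 * stride * max_steps + 10.0


def _run_one(
    params: RunnerParams,
    terrain_spec: TerrainSpec,
    max_steps: int,
    seed: int,
    trial: int,
    key: tuple,
    eps_hat_buf: np.ndarray,
    theta_buf: np.ndarray,
):
    """One trial via the compiled kernel, with automatic terrain extension."""
    eps_hat_buf.fill(np.nan)
    theta_buf.fill(np.nan)
    step_like = terrain_spec.kind is TerrainKind.STEP_LIKE
    lam = terrain_spec.lambda_
    x0 = -2.0
    extent = _trial_extent(params, max_steps)
    open_loop = params.strategy is Strategy.OPEN_LOOP
    lab_frame = params.pushoff_frame is PushoffFrame.LABORATORY_FIXED

    noise_rng = np.random.default_rng(
        np.random.SeedSequence((seed, *key, trial, 1))
    )
    etas = (
        noise_rng.uniform(-1.0, 1.0, size=max_steps)
        if params.delta_eps_t > 0
        else np.zeros(max_steps)
    )

    for _attempt in range(6):
        n_nodes = int(math.ceil((extent - x0) / lam)) + 2
        terr_rng = np.random.default_rng(
            np.random.SeedSequence((seed, *key, trial, 0))
        )
        heights = terrain_spec.dist.sample(n_nodes, terr_rng)
        steps, outcome = _kernels.run_trial_kernel(
            heights, x0, lam, step_like,
            params.I_G, params.eps_n, params.eps_tc, params.phi_tol,
            params.v_x0, params.v_y0, open_loop, params.delta_eps_t,
            params.v_stop, lab_frame, etas, max_steps,
            eps_hat_buf, theta_buf,
        )
        if outcome != _kernels.OUTCOME_RAN_OFF_TERRAIN:
            return steps, outcome
        extent *= 2.0
    raise RuntimeError(f"trial {trial}: terrain extension failed repeatedly")


def run_ensemble(
    params: RunnerParams,
    terrain_spec: TerrainSpec,
    M: int,
    max_steps: int = 1000,
    seed: int = 0,
    key: tuple = (),
) -> EnsembleStats:
    """Simulate M independent trials and aggregate failure statistics.

    Deterministic given ``seed`` (and the optional stream ``key`` prefix used
    by parameter sweeps): trial ``i`` draws its terrain from the stream
    ``(seed, *key, i, 0)`` and its control noise from ``(seed, *key, i, 1)``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    steps = np.empty(M, dtype=np.int64)
    modes = np.empty(M, dtype=np.int64)
    k_eps = min(max_steps, _EPS_HAT_STEPS)
    eps_hat = np.full((M, k_eps), np.nan)
    eps_hat_buf = np.empty(max_steps)
    theta_buf = np.empty(max_steps)

    for i in range(M):
        s, outcome = _run_one(
            params, terrain_spec, max_steps, seed, i, key,
            eps_hat_buf, theta_buf,
        )
        if outcome == _kernels.OUTCOME_NO_TOUCHDOWN:
            raise RuntimeError(f"trial {i}: touchdown search failed")
        steps[i] = s
        modes[i] = outcome
        eps_hat[i, :] = eps_hat_buf[:k_eps]

    failed = modes != _kernels.OUTCOME_CENSORED
    n_failed = int(np.sum(failed))
    if n_failed:
        mean_steps = float(np.mean(steps[failed]))
        sd_steps = float(np.std(steps[failed], ddof=1)) if n_failed > 1 else 0.0
    else:
        mean_steps = math.nan
        sd_steps = math.nan

    fractions = {
        name: float(np.mean(modes == code)) for code, name in _MODE_NAMES.items()
    }

    smax = int(np.max(steps))
    hist = np.bincount(steps, minlength=smax + 1)
    survival = 1.0 - np.concatenate([[0], np.cumsum(hist)[:-1]]) / M

    return EnsembleStats(
        M=M, max_steps=max_steps, seed=seed, params=params,
        terrain=terrain_spec, mean_steps=mean_steps, sd_steps=sd_steps,
        failure_mode_fractions=fractions, survival_curve=survival,
        steps_histogram=hist, eps_hat_by_step=eps_hat_statistics(eps_hat),
        steps=steps, modes=modes,
    )


def eps_hat_statistics(eps_hat_matrix: np.ndarray) -> pd.DataFrame:
    """Across-trial mean/sd of eps-hat at each step index.

    Rows of the input are trials, columns step indices (NaN once a trial has
    failed); only surviving trials enter each step's statistics.
    """
    eps = np.asarray(eps_hat_matrix, dtype=float)
    out = []
    for j in range(eps.shape[1]):
        col = eps[:, j]
        ok = np.isfinite(col)
        n = int(np.sum(ok))
        if n == 0:
            break
        out.append(
            {
                "step": j + 1,
                "mean": float(np.mean(col[ok])),
                "sd": float(np.std(col[ok], ddof=1)) if n > 1 else math.nan,
                "n": n,
            }
        )
    return pd.DataFrame(out, columns=["step", "mean", "sd", "n"])


def sweep_grid(
    base_params: RunnerParams,
    grid: dict,
    terrain_spec: TerrainSpec,
    M: int,
    max_steps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Ensemble statistics over a cartesian parameter grid.

    ``grid`` maps RunnerParams field names (eps_n, eps_tc, delta_eps_t) to
    value arrays.  Returns a long-format table with one row per cell
    (mean/sd steps, failure fractions) plus an ``optimal`` flag marking, for
    each delta_eps_t level, the eps_tc value maximizing mean steps.
    """
    names = list(grid)
    for name in names:
        if name not in ("eps_n", "eps_tc", "delta_eps_t"):
            raise ValueError(f"unsupported sweep axis: {name}")
    mesh = np.meshgrid(*[np.asarray(grid[n], dtype=float) for n in names],
                       indexing="ij")
    cells = np.stack([m.ravel() for m in mesh], axis=1)

    rows = []
    for ci, cell in enumerate(cells):
        p = base_params.replace(**{n: float(v) for n, v in zip(names, cell)})
        stats = run_ensemble(
            p, terrain_spec, M, max_steps=max_steps, seed=seed, key=(ci,)
        )
        row = {n: float(v) for n, v in zip(names, cell)}
        row.update(
            mean_steps=stats.mean_steps,
            sd_steps=stats.sd_steps,
            sem_steps=stats.sem_steps,
            frac_orient=stats.failure_mode_fractions["orientational"],
            frac_transl=stats.failure_mode_fractions["translational"],
            frac_censored=stats.failure_mode_fractions["none"],
        )
        rows.append(row)
    df = pd.DataFrame(rows)

    df["optimal"] = False
    if "eps_tc" in names:
        group_cols = [n for n in names if n != "eps_tc"]
        if group_cols:
            idx = df.groupby(group_cols)["mean_steps"].idxmax()
        else:
            idx = [df["mean_steps"].idxmax()]
        df.loc[idx, "optimal"] = True
    return df
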