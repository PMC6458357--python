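"""Random piecewise-linear (rough) and piecewise-constant (step-like) terrains.

A terrain is an ordered grid of node abscissae with spacing ``lambda_`` and
random node heights, interpolated linearly (rough) or held constant per cell
(step-like).  Node heights are i.i.d. draws from a configurable distribution
family, affinely rescaled to zero mean and a target range, so terrains with
different underlying shapes are directly comparable.  Because the grid
spacing is much shorter than a stride, successive contacts see effectively
uncorrelated height and slope perturbations.

Corners of a piecewise-linear profile have indeterminate slope, so queries
blend the two adjacent segment slopes linearly inside a small window around
each node ("node-slope smoothing"), giving a continuous effective slope
field.
"""

from __future__ import annotations

import enum
import functools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "TerrainKind",
    "DistSpec",
    "Terrain",
    "TerrainSpec",
    "generate_rough_terrain",
    "generate_step_terrain",
    "flat_terrain",
    "rms_slope_angle",
    "read_terrain_csv",
    "write_terrain_csv",
    "NODE_SMOOTHING_FRACTION",
]

#: Half-width of the node slope-blending window, as a fraction of the spacing.
NODE_SMOOTHING_FRACTION = 0.01


@functools.lru_cache(maxsize=None)
def _vonmises_linear_std(kappa: float) -> float:
    """Linear (not circular) standard deviation of von Mises on (-pi, pi]."""
    return float(stats.vonmises(kappa).std())


class TerrainKind(str, enum.Enum):
    ROUGH = "rough"
    STEP_LIKE = "step_like"
    FLAT = "flat"


@dataclass(frozen=True)
class DistSpec:
    """Node-height distribution: family, shape parameters, and target range.

    Samples are affinely rescaled so the population mean is 0 and the
    population support spans ``range_`` (e.g. 0.06 leg lengths gives heights
    in [-0.03, 0.03] for the uniform family).
    """

    family: str = "uniform"
    range_: float = 0.06
    kappa: float = 6.0       # von Mises concentration
    alpha: float = 1.9       # beta shape a
    beta: float = 2.3        # beta shape b

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "von_mises", "beta", "constant"):
            raise ValueError(f"unknown height distribution family: {self.family!r}")
        if self.range_ < 0:
            raise ValueError(f"range must be >= 0, got {self.range_}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n i.i.d. heights rescaled to mean 0 and support range_."""
        if self.range_ == 0.0 or self.family == "constant":
            return np.zeros(n)
        if self.family == "uniform":
            return rng.uniform(-self.range_ / 2, self.range_ / 2, size=n)
        if self.family == "von_mises":
            # mean 0 on (-pi, pi]; rescaled so the height standard deviation
            # matches the uniform family at the same nominal range
            # (range_/sqrt(12)), which is what makes terrains of different
            # shape families statistically comparable
            raw = rng.vonmises(0.0, self.kappa, size=n)
            return raw * (self.range_ / math.sqrt(12.0) / self._vonmises_std())
        # beta: support [0, 1], mean a/(a+b); shift mean to 0, scale to range_
        raw = rng.beta(self.alpha, self.beta, size=n)
        return (raw - self.alpha / (self.alpha + self.beta)) * self.range_

    def _vonmises_std(self) -> float:
        return _vonmises_linear_std(self.kappa)

    def height_variance(self) -> float:
        """Population variance of the rescaled node heights."""
        if self.range_ == 0.0 or self.family == "constant":
            return 0.0
        if self.family in ("uniform", "von_mises"):
            return self.range_**2 / 12.0
        return stats.beta(self.alpha, self.beta).var() * self.range_**2

    def to_dict(self) -> dict:
        return {
            "family": self.family, "range": self.range_,
            "kappa": self.kappa, "alpha": self.alpha, "beta": self.beta,
        }


@dataclass
class Terrain:
    """Piecewise-linear or piecewise-constant ground profile.

    ``nodes`` are strictly increasing abscissae (uniform spacing for
    generated terrains); ``heights`` the matching node heights.  For
    ``step_like`` terrains, ``heights[i]`` is the tread height on
    ``[nodes[i], nodes[i+1])`` and risers are excluded contact zones.
    """

    nodes: np.ndarray
    heights: np.ndarray
    kind: TerrainKind = TerrainKind.ROUGH
    dist_spec: Optional[DistSpec] = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.kind = TerrainKind(self.kind)
        if self.nodes.ndim != 1 or self.nodes.size < 2:
            raise ValueError("terrain needs at least two nodes")
        if self.nodes.size != self.heights.size:
            raise ValueError("nodes and heights must have equal length")
        if not np.all(np.diff(self.nodes) > 0):
            raise ValueError("node abscissae must be strictly increasing")

    @property
    def extent(self) -> tuple:
        return float(self.nodes[0]), float(self.nodes[-1])

    @property
    def lambda_(self) -> float:
        return float(self.nodes[1] - self.nodes[0])

    def _check_range(self, x: np.ndarray) -> None:
        lo, hi = self.extent
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(
                f"query x outside terrain extent [{lo}, {hi}]"
            )

    def height(self, x):
        """Terrain height at x (linear interpolation; treads for step-like)."""
        x = np.asarray(x, dtype=float)
        self._check_range(x)
        if self.kind is TerrainKind.STEP_LIKE:
            i = np.clip(
                np.searchsorted(self.nodes, x, side="right") - 1,
                0, self.nodes.size - 2,
            )
            out = self.heights[i]
        else:
            out = np.interp(x, self.nodes, self.heights)
        return float(out) if np.isscalar(out) or out.ndim == 0 else out

    def slope_angle(self, x):
        """Effective slope angle at x (radians).

        Interior of a segment: the segment slope.  Within the node-smoothing
        window (half-width ``NODE_SMOOTHING_FRACTION * lambda``): a linear
        blend of the two adjacent segment gradients.  Step-like terrains are
        flat everywhere (risers are excluded contact zones).
        """
        x = np.asarray(x, dtype=float)
        self._check_range(x)
        if self.kind in (TerrainKind.STEP_LIKE, TerrainKind.FLAT):
            out = np.zeros_like(x)
            return float(out) if out.ndim == 0 else out
        grads = np.diff(self.heights) / np.diff(self.nodes)
        scalar = x.ndim == 0
        xv = np.atleast_1d(x)
        seg = np.clip(np.searchsorted(self.nodes, xv, side="right") - 1,
                      0, grads.size - 1)
        g = grads[seg].copy()
        delta = NODE_SMOOTHING_FRACTION * np.min(np.diff(self.nodes))
        # blend across interior nodes 1..n-2
        for k, xi in enumerate(xv):
            j = int(np.argmin(np.abs(self.nodes - xi)))
            if 0 < j < self.nodes.size - 1 and abs(xi - self.nodes[j]) < delta:
                gl, gr = grads[j - 1], grads[j]
                w = (xi - self.nodes[j] + delta) / (2 * delta)  # 0 at left edge
                g[k] = (1 - w) * gl + w * gr
        ang = np.arctan(g)
        return float(ang[0]) if scalar else ang

    def query(self, x):
        """(height, slope_angle) at x."""
        return self.height(x), self.slope_angle(x)


def generate_rough_terrain(
    lambda_: float,
    dist_spec: DistSpec,
    extent: float,
    rng: np.random.Generator,
    x_start: float = -2.0,
) -> Terrain:
    """Rough terrain: i.i.d. node heights at spacing lambda_, linearly
    interpolated.  ``extent`` is the forward length covered (from x_start)."""
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    n = int(math.ceil((extent - x_start) / lambda_)) + 2
    nodes = x_start + lambda_ * np.arange(n)
    heights = dist_spec.sample(n, rng)
    kind = TerrainKind.FLAT if dist_spec.range_ == 0 else TerrainKind.ROUGH
    return Terrain(nodes=nodes, heights=heights, kind=kind, dist_spec=dist_spec)


def generate_step_terrain(
    lambda_: float,
    height_dist: DistSpec,
    extent: float,
    rng: np.random.Generator,
    x_start: float = -2.0,
) -> Terrain:
    """Step-like terrain: piecewise-constant tread heights per cell of width
    lambda_; slope is zero everywhere and risers are excluded contact zones."""
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    n = int(math.ceil((extent - x_start) / lambda_)) + 2
    nodes = x_start + lambda_ * np.arange(n)
    heights = height_dist.sample(n, rng)
    kind = TerrainKind.FLAT if height_dist.range_ == 0 else TerrainKind.STEP_LIKE
    return Terrain(nodes=nodes, heights=heights, kind=kind, dist_spec=height_dist)


@dataclass(frozen=True)
class TerrainSpec:
    """Recipe for generating one terrain realization per Monte Carlo trial."""

    kind: TerrainKind = TerrainKind.ROUGH
    lambda_: float = 0.1
    dist: DistSpec = field(default_factory=DistSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", TerrainKind(self.kind))
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")

    def build(self, extent: float, rng: np.random.Generator) -> Terrain:
        if self.kind is TerrainKind.STEP_LIKE:
            return generate_step_terrain(self.lambda_, self.dist, extent, rng)
        if self.kind is TerrainKind.FLAT:
            return flat_terrain(extent)
        return generate_rough_terrain(self.lambda_, self.dist, extent, rng)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value, "lambda": self.lambda_,
            "dist": self.dist.to_dict(),
        }


def flat_terrain(extent: float = 100.0, x_start: float = -2.0) -> Terrain:
    nodes = np.array([x_start, x_start + extent])
    return Terrain(nodes=nodes, heights=np.zeros(2), kind=TerrainKind.FLAT)


def rms_slope_angle(dist_spec: DistSpec, lambda_: float) -> float:
    """R.m.s. slope angle of a rough terrain: successive i.i.d. node heights
    give segment gradient variance 2*Var(h)/lambda^2."""
    return math.atan(math.sqrt(2.0 * dist_spec.height_variance()) / lambda_)


def read_terrain_csv(path, kind: TerrainKind = TerrainKind.ROUGH) -> Terrain:
    """Read a terrain from CSV with header ``x,h`` (nondimensional units)."""
    import pandas as pd

    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["x", "h"]:
        raise ValueError(f"terrain CSV must have header 'x,h', got {list(df.columns)}")
    return Terrain(nodes=df["x"].to_numpy(), heights=df["h"].to_numpy(), kind=kind)


def write_terrain_csv(terrain: Terrain, path) -> None:
    import pandas as pd

    pd.DataFrame({"x": terrain.nodes, "h": terrain.heights}).to_csv(path, index=False)
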