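import math

import numpy as np
import pytest

from runsim.model_core import RunnerParams
from runsim.terrain import DistSpec, TerrainSpec, flat_terrain


@pytest.fixture
def human_like():
    """Human-like open-loop runner (the reference parameter set)."""
    return RunnerParams()


@pytest.fixture
def anticipatory():
    def make(**kw):
        kw.setdefault("strategy", "anticipatory")
        return RunnerParams(**kw)

    return make


@pytest.fixture
def flat():
    return flat_terrain(extent=300.0, x_start=-50.0)


@pytest.fixture(scope="session")
def rough_spec():
    """Reference rough terrain: uniform heights U(-0.03, 0.03), spacing 0.1."""
    return TerrainSpec(kind="rough", lambda_=0.1, dist=DistSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
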