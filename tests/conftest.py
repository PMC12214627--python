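import math

import numpy as np
import pytest

from preyflock import default_params
from preyflock.state import empty_world


@pytest.fixture
def params():
    """Small, fast parameter set for unit tests (defaults otherwise)."""
    from dataclasses import replace
    return replace(default_params(), N=20, N_p=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_world(params, rng, spread=20.0, n_dead=0):
    """A random but valid world used by force-equivalence tests."""
    w = empty_world(params)
    centre = params.L / 2
    w.prey_x = (centre + rng.uniform(-spread, spread, (params.N, 2))) % params.L
    w.prey_v = rng.normal(0.0, 0.6, (params.N, 2))
    speeds = np.linalg.norm(w.prey_v, axis=1)
    w.prey_heading = w.prey_v / speeds[:, None]
    if n_dead:
        w.mu[rng.choice(params.N, n_dead, replace=False)] = 0
    w.prey_mode[:] = rng.integers(0, 2, params.N)
    ed = rng.normal(0.0, 1.0, (params.N, 2))
    w.escape_dir = ed / np.linalg.norm(ed, axis=1, keepdims=True)
    w.pred_x = (centre + rng.uniform(-spread, spread, (params.N_p, 2))) % params.L
    w.pred_v = rng.normal(0.0, 0.6, (params.N_p, 2))
    w.pred_heading = w.pred_v / np.linalg.norm(w.pred_v, axis=1, keepdims=True)
    w.pred_mode[:] = 0  # pursuit
    w.pred_target[:] = rng.integers(0, params.N, params.N_p)
    return w


@pytest.fixture
def two_pi():
    return 2 * math.pi
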