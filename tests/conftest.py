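import numpy as np
import pytest

from kinsim.engine import Society
from kinsim.params import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    return ModelParams(N_s=3, N_f=5, d_c=0.3, d_m=0.2, n_steps=10, seed=7)


def make_society(t, p, men=None, women=None, pending=None, lifespan=2,
                 society_id=0):
    """Build a Society from plain arrays (test helper)."""
    t = np.asarray(t, dtype=float).reshape(-1, 2)
    p = np.asarray(p, dtype=float).reshape(-1, 2)
    n = len(t)
    if men is None:
        men = np.zeros((n, lifespan), np.int64)
    if women is None:
        women = np.zeros((n, lifespan), np.int64)
    if pending is None:
        pending = np.zeros(n, bool)
    return Society(
        society_id, society_id, t, p,
        np.asarray(men, np.int64).reshape(n, -1),
        np.asarray(women, np.int64).reshape(n, -1),
        np.arange(n, dtype=np.int64), np.zeros(n, np.int64),
        np.asarray(pending, bool),
    )
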