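import numpy as np
import pytest

from flockinf.generative_model import ModelParams
from flockinf.world import SwarmState


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_scene(rng, n_agents, spread=3.0, informed_mask=None, target=None,
                 params=None):
    """Random positions/headings with beliefs seeded near the scene."""
    params = params or ModelParams()
    pos = rng.uniform(-spread, spread, (n_agents, 2))
    ang = rng.uniform(0, 2 * np.pi, n_agents)
    head = np.column_stack([np.cos(ang), np.sin(ang)])
    if informed_mask is None:
        informed_mask = np.zeros(n_agents, dtype=bool)
    M = params.L + (1 if np.any(informed_mask) else 0)
    mu = rng.normal(params.eta, 0.5, (n_agents, M, params.n_orders_x))
    return SwarmState(pos, head, mu, np.full(n_agents, params.lambda_z),
                      np.asarray(informed_mask, bool), 0.0,
                      None if target is None else np.asarray(target, float))


@pytest.fixture
def scene_factory():
    return random_scene
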