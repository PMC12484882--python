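import numpy as np
import pytest

from omnimol.model import ModelConfig, OmniMolModel
from omnimol.molgraph import Conformation, build_graph
from omnimol.tmoe import TaskMeta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_conformation(rng):
    """A compact 8-atom molecule with generic (non-degenerate) geometry."""
    return Conformation(np.array([6, 9, 8, 7, 6, 6, 7, 8]),
                        rng.normal(0.0, 1.4, size=(8, 3)), mol_id="random8")


@pytest.fixture
def random_graph(random_conformation):
    return build_graph(random_conformation, cutoff=3.5)


@pytest.fixture
def small_config():
    return ModelConfig(n_layers_per_block=1, n_recycles=2, hidden_dim=16,
                       n_heads=2, n_experts=2, d_emb=8, n_basis=8, Omega=2,
                       cutoff=3.5)


@pytest.fixture
def small_model(small_config):
    return OmniMolModel(small_config, seed=0)


@pytest.fixture
def cls_meta():
    return TaskMeta(task_id=0, task_type="classification", group="toxicity",
                    positive_ratio=0.4)


@pytest.fixture
def reg_meta():
    return TaskMeta(task_id=1, task_type="regression", group="physicochemical",
                    target_mean=1.2, target_std=0.8)


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
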