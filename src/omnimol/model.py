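"""OmniMol model assembly: layers, blocks, recycling, readout, heads.

A forward pass encodes a conformation into SE(3)-invariant node/edge
features, runs S recycled blocks — each a stack of transformer layers
(self-attention with an additive per-edge bias, then the task-routed MoE)
followed by one positional update — and pools node features with a
node-level softmax attention readout into a graph embedding and a
task-type-appropriate prediction. Positions are refined in place across
blocks, so the trajectory P^0 … P^S is part of the output.

Geometry recomputation between blocks is detached: gradients reach the
geometry pathway through the per-edge magnitude predictions (supervised at
the edge level), not through the closed-form reconstruction.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from ._autodiff import Tensor, concat, gather, scatter_add
from .drlabel import PositionalUpdateHead
from .molgraph import Conformation, MolecularGraph, build_graph
from .se3 import SE3Encoder
from .tmoe import MoE, Router, TaskMeta, TaskMetaEncoder

__all__ = ["ModelConfig", "ModelOutput", "OmniMolLayer", "OmniMolBlock",
           "OmniMolModel", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    n_layers_per_block: int = 3
    n_recycles: int = 4          # S: number of positional-update blocks
    hidden_dim: int = 128
    n_heads: int = 8
    n_experts: int = 8           # N_M
    Omega: int = 4
    d_emb: int = 64
    n_basis: int = 32
    cutoff: float = 5.0
    min_neighbors: int = 3
    use_torsion: bool = True
    share_recycle_weights: bool = True
    reg_eps: float = 1e-6
    max_tasks: int = 256

    def __post_init__(self):
        if self.n_recycles < 1:
            raise ValueError("n_recycles (S) must be >= 1")
        for name in ("n_layers_per_block", "hidden_dim", "n_heads", "n_experts",
                     "Omega", "d_emb", "n_basis"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")


@dataclass
class ModelOutput:
    graph_embedding: np.ndarray
    node_attention: np.ndarray
    prediction: float
    trajectory: list            # S + 1 position arrays, P^0 … P^S
    per_layer_node_features: list | None = None
    # tensors retained for training (graphs are states P^{x-1} per block)
    prediction_tensor: Tensor | None = field(default=None, repr=False)
    m_tensors: list = field(default_factory=list, repr=False)
    block_graphs: list = field(default_factory=list, repr=False)


class MultiHeadAttention(nn.Module):
    """Self-attention over the nodes of one molecule with additive edge bias.

    The bias adds, per head, a learned linear functional of the edge feature
    on bonded pairs, a shared learned scalar on non-bonded pairs, and a
    learned scalar on the diagonal; full (dense) attention is retained.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.out = nn.Linear(dim, dim, rng)
        self.edge_bias = nn.Linear(dim, n_heads, rng)
        self.no_edge_bias = nn.Parameter(np.zeros(n_heads))
        self.self_bias = nn.Parameter(np.zeros(n_heads))

    def _bias(self, edge_feats: Tensor, graph: MolecularGraph, n: int) -> Tensor:
        vals = self.edge_bias(edge_feats)                       # (E, h)
        flat_idx = graph.edges[:, 0] * n + graph.edges[:, 1]
        bias = scatter_add(vals, flat_idx, n * n)               # (n², h)
        no_edge_mask = np.ones(n * n)
        no_edge_mask[flat_idx] = 0.0
        no_edge_mask[:: n + 1] = 0.0                            # diagonal handled below
        eye = np.eye(n).reshape(-1)
        bias = bias + Tensor(no_edge_mask[:, None]) * self.no_edge_bias
        bias = bias + Tensor(eye[:, None]) * self.self_bias
        return bias.reshape(n, n, self.n_heads).transpose(2, 0, 1)

    def forward(self, X: Tensor, edge_feats: Tensor, graph: MolecularGraph) -> Tensor:
        n = X.shape[0]
        qkv = self.qkv(X).reshape(n, 3, self.n_heads, self.d_head).transpose(1, 2, 0, 3)
        q, k, v = qkv[0], qkv[1], qkv[2]                        # each (h, n, d_head)
        scores = q @ k.transpose(0, 2, 1) * (1.0 / np.sqrt(self.d_head))
        scores = scores + self._bias(edge_feats, graph, n)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(1, 0, 2).reshape(n, self.n_heads * self.d_head)
        return self.out(out)


class OmniMolLayer(nn.Module):
    """Self-attention + t-MoE with residual connections and layer norms."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(cfg.hidden_dim, cfg.n_heads, rng)
        self.moe = MoE(cfg.hidden_dim, cfg.n_experts, rng)
        self.norm1 = nn.LayerNorm(cfg.hidden_dim)
        self.norm2 = nn.LayerNorm(cfg.hidden_dim)

    def forward(self, X: Tensor, edge_feats: Tensor, graph: MolecularGraph,
                alpha: Tensor) -> Tensor:
        X = self.norm1(X + self.attn(X, edge_feats, graph))
        return self.norm2(X + self.moe(X, alpha))


class OmniMolBlock(nn.Module):
    """A stack of OmniMol layers followed by one positional update."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.layers = [OmniMolLayer(cfg, rng) for _ in range(cfg.n_layers_per_block)]
        self.pos_head = PositionalUpdateHead(cfg.hidden_dim, rng, eps=cfg.reg_eps)

    def forward(self, X: Tensor, edge_feats: Tensor, graph: MolecularGraph,
                positions: np.ndarray, alpha: Tensor, block_index: int = 0):
        for layer in self.layers:
            X = layer(X, edge_feats, graph, alpha)
        new_pos, delta, m = self.pos_head(X, edge_feats, graph, positions,
                                          block_index=block_index)
        return X, new_pos, m


class Readout(nn.Module):
    """Node-level softmax attention pooling plus task-type heads.

    A learned scalar score per node (from [node feature ‖ t_emb]) is
    softmax-normalized over the molecule; the graph embedding is the
    attention-weighted sum of node features. Regression and classification
    use separate linear heads on the shared embedding (classification through
    a logistic link).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.score = nn.FFN(cfg.hidden_dim + cfg.d_emb, cfg.hidden_dim, 1, rng)
        self.head_reg = nn.Linear(cfg.hidden_dim, 1, rng)
        self.head_cls = nn.Linear(cfg.hidden_dim, 1, rng)

    def forward(self, X: Tensor, t_emb: Tensor, task_type: str):
        n = X.shape[0]
        if n == 0:
            raise ValueError("empty molecule")
        temb_rows = Tensor(np.ones((n, 1))) * t_emb.reshape(1, -1)
        scores = self.score(concat([X, temb_rows], axis=1))       # (n, 1)
        attention = scores.softmax(axis=0)                        # (n, 1)
        graph_emb = (attention * X).sum(axis=0)                   # (d,)
        if task_type == "classification":
            pred = self.head_cls(graph_emb).sigmoid()
        else:
            pred = self.head_reg(graph_emb)
        return graph_emb, attention.reshape(-1), pred.reshape(())


class OmniMolModel(nn.Module):
    """End-to-end model: SE(3) encoder → S recycled blocks → readout."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = SE3Encoder(cfg.hidden_dim, rng, Omega=cfg.Omega,
                                  n_basis=cfg.n_basis, r_max=cfg.cutoff,
                                  use_torsion=cfg.use_torsion)
        self.task_encoder = TaskMetaEncoder(cfg.d_emb, rng, max_tasks=cfg.max_tasks)
        self.router = Router(cfg.d_emb, cfg.n_experts, rng)
        n_blocks = 1 if cfg.share_recycle_weights else cfg.n_recycles
        self.blocks = [OmniMolBlock(cfg, rng) for _ in range(n_blocks)]
        self.readout = Readout(cfg, rng)

    def block_at(self, x: int) -> OmniMolBlock:
        return self.blocks[0] if self.cfg.share_recycle_weights else self.blocks[x]

    def forward(self, conf: Conformation, meta: TaskMeta,
                keep_layer_features: bool = False) -> ModelOutput:
        cfg = self.cfg
        graph = build_graph(conf, cutoff=cfg.cutoff, min_neighbors=cfg.min_neighbors)
        t_emb = self.task_encoder(meta)
        alpha = self.router(t_emb)
        X, edge_feats = self.encoder(conf, graph)

        positions = conf.positions.copy()
        trajectory = [positions.copy()]
        m_tensors: list[Tensor] = []
        block_graphs: list[MolecularGraph] = []
        layer_feats = [] if keep_layer_features else None
        for x in range(cfg.n_recycles):
            block_graphs.append(graph)
            X, positions, m = self.block_at(x)(X, edge_feats, graph, positions,
                                               alpha, block_index=x)
            m_tensors.append(m)
            trajectory.append(positions.copy())
            if keep_layer_features:
                layer_feats.append(X.data.copy())
            if x + 1 < cfg.n_recycles:
                graph = graph.refresh_geometry(positions)
                edge_feats = self.encoder.edge_features(graph)

        graph_emb, attention, pred = self.readout(X, t_emb, meta.task_type)
        return ModelOutput(
            graph_embedding=graph_emb.data.copy(),
            node_attention=attention.data.copy(),
            prediction=float(pred.data),
            trajectory=trajectory,
            per_layer_node_features=layer_feats,
            prediction_tensor=pred,
            m_tensors=m_tensors,
            block_graphs=block_graphs,
        )


def save_checkpoint(path, model: OmniMolModel, extra: dict | None = None) -> None:
    """Weights + config + seed in one npz archive."""
    meta = {"config": asdict(model.cfg), "seed": model.seed, "extra": extra or {}}
    arrays = {"param/" + k: v for k, v in model.state_dict().items()}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[OmniMolModel, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k[len("param/"):]: archive[k] for k in archive.files
                 if k.startswith("param/")}
    model = OmniMolModel(ModelConfig(**meta["config"]), seed=meta["seed"])
    model.load_state_dict(state)
    return model, meta["extra"]
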