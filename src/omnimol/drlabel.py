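"""Edge-projection geometry labels and the closed-form sphere-fit update.

Node-level geometry supervision Δp*_i is decomposed into per-edge scalars
u_ij = d_ij·Δp*_i — independent of neighborhood size and of how the graph was
built. At inference the model predicts per-edge magnitudes m_ij; projection
vectors v_ij = m_ij·d_ij are recombined into a per-node update by fitting a
sphere through the origin:

    min_c Σ_j (||v_ij − c||² − ||c||²)²

whose stationary condition gives c_i = (2A_i)⁻¹ b_i with
b_i = mean_j (v·v) v and A_i = mean_j v vᵀ, and Δp_i = 2c_i. When the
projections are consistent (m_ij = d_ij·Δp for some Δp) and the neighbor
directions span 3D, the update is recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._autodiff import Tensor, concat, gather
from .molgraph import MolecularGraph

__all__ = ["EdgeProjection", "PositionUpdate", "decompose_labels",
           "reconstruct_update", "PositionalUpdateHead"]


@dataclass
class EdgeProjection:
    """Per-directed-edge scalar magnitudes and their projection vectors."""
    m: np.ndarray            # (E,) predicted magnitudes
    v: np.ndarray            # (E, 3) = m[:, None] * d_ij
    u: np.ndarray | None = None  # (E,) supervision scalars, when available


@dataclass
class PositionUpdate:
    delta_p: np.ndarray      # (n, 3) per-node geometry update = 2 * centers
    centers: np.ndarray      # (n, 3) fitted sphere centers c_i
    b: np.ndarray            # (n, 3) weighted mean vectors b_i
    A: np.ndarray            # (n, 3, 3) symmetric projection-covariance A_i
    reg_eps: float


def decompose_labels(delta_star: np.ndarray, graph: MolecularGraph) -> np.ndarray:
    """Edge-level supervision u_ij = d_ij · Δp*_i for every directed edge (i, j).

    Each scalar involves only the edge's own direction and the target node's
    displacement, so adding or removing other edges leaves it bitwise
    unchanged.
    """
    delta_star = np.asarray(delta_star, dtype=np.float64)
    return np.einsum("ej,ej->e", graph.directions, delta_star[graph.edges[:, 0]])


def projection_vectors(m: np.ndarray, graph: MolecularGraph) -> EdgeProjection:
    m = np.asarray(m, dtype=np.float64)
    return EdgeProjection(m=m, v=m[:, None] * graph.directions)


def reconstruct_update(proj: EdgeProjection, graph: MolecularGraph,
                       eps: float = 1e-6) -> PositionUpdate:
    """Closed-form per-node update from edge projections.

    ``eps`` is added to 2A_i before inversion to cover near-coplanar
    neighborhoods; with ``eps = 0`` a singular A_i raises, naming the node.
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    n = graph.n_nodes
    v = proj.v
    w = np.einsum("ej,ej->e", v, v)              # ||v_ij||²
    tgt = graph.edges[:, 0]
    counts = np.bincount(tgt, minlength=n).astype(np.float64)
    if np.any(counts == 0):
        raise ValueError(f"node {int(np.where(counts == 0)[0][0])} has no neighbors")

    b = np.zeros((n, 3))
    np.add.at(b, tgt, w[:, None] * v)
    b /= counts[:, None]
    A = np.zeros((n, 3, 3))
    np.add.at(A, tgt, v[:, :, None] * v[:, None, :])
    A /= counts[:, None, None]

    M = 2.0 * A + eps * np.eye(3)
    if eps == 0.0:
        sing = np.abs(np.linalg.det(M)) < 1e-300
        # also catch numerically rank-deficient but nonzero-det cases
        if np.any(sing):
            raise np.linalg.LinAlgError(
                f"A singular at node {int(np.where(sing)[0][0])}; pass eps > 0")
        try:
            centers = np.linalg.solve(M, b[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"A singular ({exc}); pass eps > 0") from exc
    else:
        centers = np.linalg.solve(M, b[..., None])[..., 0]
    return PositionUpdate(delta_p=2.0 * centers, centers=centers, b=b, A=A, reg_eps=eps)


class PositionalUpdateHead(nn.Module):
    """Predicts per-edge magnitudes m and applies the sphere-fit update.

    m_ij comes from a two-layer feed-forward map (GeLU) on the concatenated
    endpoint node features and edge feature; positions advance to
    P^x = P^{x−1} + Δp. Because m is an SE(3)-invariant scalar and the
    reconstruction composes it with the directions d_ij, the update is
    SE(3)-equivariant. Gradients flow through m only (the reconstruction is
    applied to detached values); supervision is the edge-level u scalars.
    """

    def __init__(self, hidden_dim: int, rng: np.random.Generator, eps: float = 1e-6):
        super().__init__()
        self.mlp = nn.FFN(3 * hidden_dim, hidden_dim, 1, rng)
        self.eps = eps

    def predict_m(self, node_feats: Tensor, edge_feats: Tensor,
                  graph: MolecularGraph) -> Tensor:
        src = gather(node_feats, graph.edges[:, 0])
        dst = gather(node_feats, graph.edges[:, 1])
        m = self.mlp(concat([src, dst, edge_feats], axis=1))
        return m.reshape(-1)

    def forward(self, node_feats: Tensor, edge_feats: Tensor,
                graph: MolecularGraph, positions: np.ndarray,
                block_index: int = 0):
        """Returns (new_positions, delta_p, m_tensor)."""
        m = self.predict_m(node_feats, edge_feats, graph)
        if not np.isfinite(m.data).all():
            raise FloatingPointError(f"non-finite magnitude prediction in block {block_index}")
        update = reconstruct_update(projection_vectors(m.data, graph), graph, eps=self.eps)
        return positions + update.delta_p, update.delta_p, m
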