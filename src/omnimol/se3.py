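"""Chirality-aware SE(3) edge featurization.

The geometric primitives here are pure functions of the molecular graph:

* ``chirality_vectors`` — per directed edge (i, j), the permutation-invariant
  cross-product sum c_ij = Σ_{k∈N_i∖{j}} d_ij × d_ik (and c_ji symmetrically).
* ``torsion_angles`` — the chirality-aware torsion
  ψ_ij = asin(⟨(c_ij × c_ji)/(|c_ij||c_ji|), d_ij⟩), invariant under rotation
  and translation but negated under reflection, which is what lets the model
  tell enantiomers apart.
* ``circular_harmonics`` — the sin(ωψ)/cos(ωψ) basis over ω ∈ {−Ω..Ω}. The
  sine block (degree l=1) carries the reflection sensitivity; the cosine block
  (l=−1) is reflection-invariant.
* ``radial_embedding`` — Gaussian radial basis of the edge length.

``SE3Encoder`` assembles these into learned initial node and edge features.
Degenerate edges (collinear or planar neighborhoods where a chirality vector
vanishes) get ψ = 0 with ``valid = False`` rather than NaN, so planar
molecules encode cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._autodiff import Tensor, concat, scatter_add
from .io import ELEMENT_SYMBOLS
from .molgraph import Conformation, MolecularGraph

__all__ = ["ChiralityVectors", "TorsionFeatures", "chirality_vectors",
           "torsion_angles", "circular_harmonics", "radial_embedding",
           "SE3Encoder", "DEGENERACY_TOL"]

DEGENERACY_TOL = 1e-8  # chirality-vector norm below which an edge is degenerate


@dataclass
class ChiralityVectors:
    """Per-directed-edge cross-product vectors c_ij and the reverse c_ji."""
    c_ij: np.ndarray      # (E, 3), aligned with graph.edges
    c_ji: np.ndarray      # (E, 3) = c of the reverse edge
    degenerate_mask: np.ndarray  # (E,) bool — either vector has near-zero norm


@dataclass
class TorsionFeatures:
    psi: np.ndarray    # (E,) radians in [-pi/2, pi/2]; 0 on degenerate edges
    valid: np.ndarray  # (E,) bool


def chirality_vectors(graph: MolecularGraph) -> ChiralityVectors:
    """Permutation-invariant chirality vectors for every directed edge.

    Uses the bilinearity of the cross product: since d_ij × d_ij = 0 the
    excluded-neighbor sum collapses to c_ij = d_ij × Σ_{k∈N_i} d_ik.
    """
    n = graph.n_nodes
    # per-node sum of outgoing directions Σ_k d_ik
    s = np.zeros((n, 3))
    np.add.at(s, graph.edges[:, 0], graph.directions)
    c_ij = np.cross(graph.directions, s[graph.edges[:, 0]])
    c_ji = c_ij[graph.reverse_index]
    norms_ij = np.linalg.norm(c_ij, axis=1)
    degenerate = (norms_ij < DEGENERACY_TOL) | (norms_ij[graph.reverse_index] < DEGENERACY_TOL)
    return ChiralityVectors(c_ij, c_ji, degenerate)


def torsion_angles(cv: ChiralityVectors, graph: MolecularGraph) -> TorsionFeatures:
    """Chirality-aware torsion angle per edge; ψ_ij = ψ_ji by construction."""
    cross = np.cross(cv.c_ij, cv.c_ji)
    denom = np.linalg.norm(cv.c_ij, axis=1) * np.linalg.norm(cv.c_ji, axis=1)
    valid = ~cv.degenerate_mask
    arg = np.zeros(graph.n_edges)
    arg[valid] = np.einsum("ij,ij->i", cross[valid], graph.directions[valid]) / denom[valid]
    psi = np.arcsin(np.clip(arg, -1.0, 1.0))
    psi[~valid] = 0.0
    return TorsionFeatures(psi, valid)


def circular_harmonics(psi: np.ndarray | TorsionFeatures, Omega: int) -> np.ndarray:
    """Circular-harmonic embedding of the torsion angle.

    Returns an (E, 2·(2Ω+1)) array: first the degree l=1 block sin(ωψ) for
    ω = −Ω..Ω, then the l=−1 block cos(ωψ) in the same ω order.
    """
    if Omega < 1:
        raise ValueError(f"Omega must be >= 1, got {Omega}")
    angles = psi.psi if isinstance(psi, TorsionFeatures) else np.asarray(psi, dtype=np.float64)
    omegas = np.arange(-Omega, Omega + 1)
    wpsi = angles[:, None] * omegas[None, :]
    return np.concatenate([np.sin(wpsi), np.cos(wpsi)], axis=1)


def radial_embedding(lengths: np.ndarray, n_basis: int = 32, r_max: float = 5.0) -> np.ndarray:
    """Gaussian radial basis of edge lengths.

    ``n_basis`` centers evenly spaced on [0, r_max] with width equal to the
    spacing; each activation lies in (0, 1] and equals 1 exactly at a center.
    """
    if r_max <= 0:
        raise ValueError(f"r_max must be positive, got {r_max}")
    lengths = np.asarray(lengths, dtype=np.float64)
    if np.any(lengths <= 0):
        raise ValueError("edge lengths must be positive")
    centers = np.linspace(0.0, r_max, n_basis)
    width = r_max / (n_basis - 1) if n_basis > 1 else r_max
    return np.exp(-0.5 * ((lengths[:, None] - centers[None, :]) / width) ** 2)


def edge_feature_matrix(graph: MolecularGraph, Omega: int, n_basis: int,
                        r_max: float, use_torsion: bool = True) -> np.ndarray:
    """Raw concatenated [harmonics ‖ radial] features, recomputable per state.

    With ``use_torsion`` off the harmonic block is zeroed, leaving a purely
    distance-based (hence reflection-invariant) featurization.
    """
    harm = circular_harmonics(torsion_angles(chirality_vectors(graph), graph), Omega)
    if not use_torsion:
        harm = np.zeros_like(harm)
    rad = radial_embedding(graph.lengths, n_basis, r_max)
    return np.concatenate([harm, rad], axis=1)


class SE3Encoder(nn.Module):
    """Initial node/edge embeddings from geometry and composition.

    Node features: a learned atomic-number embedding plus sum-pooled edge
    embeddings over incoming edges. Edge features: the [harmonic ‖ radial]
    vector through a learned affine map.
    """

    MAX_Z = max(ELEMENT_SYMBOLS) + 1

    def __init__(self, hidden_dim: int, rng: np.random.Generator, Omega: int = 4,
                 n_basis: int = 32, r_max: float = 5.0, use_torsion: bool = True):
        super().__init__()
        self.Omega = Omega
        self.n_basis = n_basis
        self.r_max = r_max
        self.use_torsion = use_torsion
        d_edge_raw = 2 * (2 * Omega + 1) + n_basis
        self.element_embedding = nn.Embedding(self.MAX_Z, hidden_dim, rng)
        self.edge_map = nn.Linear(d_edge_raw, hidden_dim, rng)

    def _check_elements(self, elements: np.ndarray) -> None:
        bad = set(int(z) for z in elements) - set(ELEMENT_SYMBOLS)
        if bad:
            raise ValueError(f"unknown element(s) {sorted(bad)}; supported atomic "
                             f"numbers: {sorted(ELEMENT_SYMBOLS)}")

    def edge_features(self, graph: MolecularGraph) -> Tensor:
        raw = edge_feature_matrix(graph, self.Omega, self.n_basis, self.r_max,
                                  self.use_torsion)
        return self.edge_map(Tensor(raw))

    def forward(self, conf: Conformation, graph: MolecularGraph):
        """Returns (node_features (n, d), edge_features (E, d)) tensors."""
        self._check_elements(conf.elements)
        edge_feats = self.edge_features(graph)
        node_feats = self.element_embedding(conf.elements) + scatter_add(
            edge_feats, graph.edges[:, 0], graph.n_nodes)
        return node_feats, edge_feats
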