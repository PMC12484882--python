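"""Conformation containers and radius-graph construction.

A :class:`Conformation` holds atomic numbers and Cartesian coordinates (Å),
optionally together with an equilibrium geometry and the perturbation that
produced the current positions from it. A :class:`MolecularGraph` is the
directed radius graph all geometric operations run on: per-edge unit
direction vectors ``d_ij = (p_i - p_j)/||p_i - p_j||`` (pointing from atom j
toward atom i), edge lengths, and per-node neighbor sets.

Graph construction augments under-connected nodes with their nearest atoms
until every node has at least ``min_neighbors`` neighbors. On molecules with
four or more atoms this keeps each node's neighbor directions spanning 3D
(non-coplanar), the precondition of the sphere-fit geometry update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["Conformation", "MolecularGraph", "build_graph", "unit_directions",
           "perturb_conformation"]


@dataclass
class Conformation:
    """Atomic numbers plus 3D coordinates in Å.

    ``positions`` is the current geometry (the state P^x being operated on).
    ``equilibrium_positions`` (P*) and ``perturbation`` (P̃, with
    P^0 = P* + P̃) are optional and carried for relaxation supervision.
    """

    elements: np.ndarray
    positions: np.ndarray
    equilibrium_positions: np.ndarray | None = None
    perturbation: np.ndarray | None = None
    mol_id: str = ""

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.elements) != len(self.positions):
            raise ValueError(
                f"{len(self.elements)} elements but {len(self.positions)} position rows")
        if not np.isfinite(self.positions).all():
            raise ValueError("non-finite coordinates")
        if self.equilibrium_positions is not None:
            self.equilibrium_positions = np.asarray(self.equilibrium_positions, dtype=np.float64)
            if self.equilibrium_positions.shape != self.positions.shape:
                raise ValueError("equilibrium_positions shape mismatch")
        if self.perturbation is not None:
            self.perturbation = np.asarray(self.perturbation, dtype=np.float64)
            if self.equilibrium_positions is None:
                raise ValueError("perturbation requires equilibrium_positions")
            if not np.allclose(self.positions,
                               self.equilibrium_positions + self.perturbation):
                raise ValueError("positions != equilibrium_positions + perturbation")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def with_positions(self, positions: np.ndarray) -> "Conformation":
        """Copy with new current positions (equilibrium retained, perturbation dropped)."""
        return Conformation(self.elements.copy(), np.asarray(positions, dtype=np.float64),
                            equilibrium_positions=None if self.equilibrium_positions is None
                            else self.equilibrium_positions.copy(),
                            mol_id=self.mol_id)

    def mirrored(self) -> "Conformation":
        """Exact mirror image (reflection through the xy-plane)."""
        flip = np.array([1.0, 1.0, -1.0])
        return Conformation(
            self.elements.copy(), self.positions * flip,
            equilibrium_positions=None if self.equilibrium_positions is None
            else self.equilibrium_positions * flip,
            perturbation=None if self.perturbation is None else self.perturbation * flip,
            mol_id=self.mol_id + "|mirror" if self.mol_id else "")


@dataclass
class MolecularGraph:
    """Directed edge list with precomputed geometry.

    ``edges[e] = (i, j)`` carries direction ``directions[e] = d_ij`` from
    atom j to atom i and length ``lengths[e] = r_ij``. The edge set is
    symmetric; ``reverse_index[e]`` locates edge (j, i). ``neighbors[i]``
    lists j over incoming edges (i, j), and ``edge_ids_of_node[i]`` the
    corresponding edge rows.
    """

    edges: np.ndarray
    directions: np.ndarray
    lengths: np.ndarray
    neighbors: list = field(repr=False)
    edge_ids_of_node: list = field(repr=False)
    reverse_index: np.ndarray = field(repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.neighbors)

    def refresh_geometry(self, positions: np.ndarray) -> "MolecularGraph":
        """Same topology, directions/lengths recomputed for new positions."""
        directions, lengths = unit_directions(positions, self.edges)
        return MolecularGraph(self.edges, directions, lengths, self.neighbors,
                              self.edge_ids_of_node, self.reverse_index)


def unit_directions(positions: np.ndarray, edges: np.ndarray):
    """Per-edge unit vectors d_ij = (p_i - p_j)/r_ij and lengths r_ij."""
    positions = np.asarray(positions, dtype=np.float64)
    edges = np.asarray(edges, dtype=np.int64)
    diff = positions[edges[:, 0]] - positions[edges[:, 1]]
    lengths = np.linalg.norm(diff, axis=1)
    if np.any(lengths == 0.0):
        bad = edges[np.where(lengths == 0.0)[0][0]]
        raise ValueError(f"zero-length edge between atoms {bad[0]} and {bad[1]}")
    return diff / lengths[:, None], lengths


def build_graph(conf: Conformation, cutoff: float = 5.0,
                min_neighbors: int = 3) -> MolecularGraph:
    """Radius graph with nearest-neighbor augmentation.

    All atom pairs within ``cutoff`` Å become edges; any node with fewer
    than ``min_neighbors`` neighbors is additionally connected to its
    nearest atoms until the quota is met. The edge set is symmetric and
    ordered lexicographically by (i, j).
    """
    n = conf.n_atoms
    if n < 2:
        raise ValueError("graph undefined for single-atom input")
    pos = conf.positions
    dist = cdist(pos, pos)
    off_diag = dist[~np.eye(n, dtype=bool)]
    if np.any(off_diag == 0.0):
        ii, jj = np.where((dist == 0.0) & ~np.eye(n, dtype=bool))
        raise ValueError(f"degenerate pair: atoms {ii[0]} and {jj[0]} coincide")

    adj = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    quota = min(min_neighbors, n - 1)
    order = np.argsort(dist, axis=1, kind="stable")
    for i in range(n):
        k = int(adj[i].sum())
        if k < quota:
            for j in order[i]:
                if j == i or adj[i, j]:
                    continue
                adj[i, j] = adj[j, i] = True
                k += 1
                if k >= quota:
                    break
    ii, jj = np.nonzero(adj)
    edges = np.stack([ii, jj], axis=1)  # nonzero is row-major -> sorted by (i, j)

    directions, lengths = unit_directions(pos, edges)
    neighbors = [edges[edges[:, 0] == i, 1] for i in range(n)]
    edge_ids_of_node = [np.nonzero(edges[:, 0] == i)[0] for i in range(n)]
    key = {(int(a), int(b)): e for e, (a, b) in enumerate(edges)}
    reverse_index = np.array([key[(int(b), int(a))] for a, b in edges], dtype=np.int64)
    return MolecularGraph(edges, directions, lengths, neighbors,
                          edge_ids_of_node, reverse_index)


def perturb_conformation(conf: Conformation, sigma: float,
                         seed: int | np.random.Generator) -> Conformation:
    """Displace an equilibrium geometry by i.i.d. Gaussian coordinate noise.

    Simulates a high-energy conformation P^0 = P* + P̃ with P̃ ~ N(0, sigma²)
    per coordinate. The equilibrium geometry is retained on the returned
    conformation for supervision.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    equilibrium = (conf.equilibrium_positions if conf.equilibrium_positions is not None
                   else conf.positions)
    noise = rng.normal(0.0, sigma, size=equilibrium.shape) if sigma > 0 \
        else np.zeros_like(equilibrium)
    return Conformation(conf.elements.copy(), equilibrium + noise,
                        equilibrium_positions=equilibrium.copy(),
                        perturbation=noise, mol_id=conf.mol_id)
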