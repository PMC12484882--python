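"""Edge-projection labels and the closed-form sphere-fit reconstruction."""

import numpy as np
import pytest
from scipy.optimize import minimize

from omnimol._autodiff import Tensor
from omnimol.drlabel import (EdgeProjection, PositionalUpdateHead,
                             decompose_labels, projection_vectors,
                             reconstruct_update)
from omnimol.molgraph import Conformation, MolecularGraph, build_graph

from conftest import random_rotation


def single_node_graph(directions: np.ndarray) -> MolecularGraph:
    """A star graph: node 0 with |directions| neighbors (for node-0 math only)."""
    k = len(directions)
    edges = np.array([[0, j + 1] for j in range(k)])
    return MolecularGraph(edges=edges, directions=directions,
                          lengths=np.ones(k), neighbors=[edges[:, 1]],
                          edge_ids_of_node=[np.arange(k)],
                          reverse_index=np.arange(k))


def sphere_fit_objective(c: np.ndarray, v: np.ndarray) -> float:
    """The printed objective: Σ_j (||v_j − c||² − ||c||²)²."""
    return float((((np.linalg.norm(v - c, axis=1) ** 2)
                   - np.dot(c, c)) ** 2).sum())


class TestDecomposeLabels:
    def test_parallel_displacement(self):
        d = np.array([[1.0, 0, 0]])
        g = single_node_graph(d)
        u = decompose_labels(np.array([[2.5, 0, 0], [0, 0, 0]]), g)
        assert u[0] == pytest.approx(2.5)

    def test_orthogonal_displacement(self):
        g = single_node_graph(np.array([[1.0, 0, 0]]))
        u = decompose_labels(np.array([[0, 3.0, 0], [0, 0, 0]]), g)
        assert u[0] == 0.0

    def test_independent_of_neighborhood(self, rng):
        """Adding edges leaves existing u values bitwise unchanged."""
        dirs = rng.normal(size=(3, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        extra = rng.normal(size=(2, 3))
        extra /= np.linalg.norm(extra, axis=1, keepdims=True)
        delta = rng.normal(size=(6, 3))
        u_small = decompose_labels(delta, single_node_graph(dirs))
        u_large = decompose_labels(delta, single_node_graph(np.vstack([dirs, extra])))
        np.testing.assert_array_equal(u_small, u_large[:3])


class TestReconstructUpdate:
    def test_zero_projections_zero_update(self, random_graph):
        upd = reconstruct_update(projection_vectors(
            np.zeros(random_graph.n_edges), random_graph), random_graph)
        np.testing.assert_array_equal(upd.delta_p, 0.0)

    def test_exact_recovery_of_consistent_projections(self, rng):
        """m_ij = d_ij·Δp with non-coplanar directions recovers Δp exactly."""
        worst = 0.0
        for _ in range(200):
            k = rng.integers(4, 13)
            dirs = rng.normal(size=(k, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            g = single_node_graph(dirs)
            dp = rng.normal(0, 0.5, size=3)
            m = dirs @ dp
            upd = reconstruct_update(projection_vectors(m, g), g, eps=0.0)
            worst = max(worst, np.abs(upd.delta_p[0] - dp).max())
        assert worst < 1e-8

    def test_matches_numerical_minimizer_on_noisy_input(self, rng):
        """c_i from the closed form equals the argmin of the printed objective."""
        for _ in range(20):
            k = rng.integers(4, 13)
            dirs = rng.normal(size=(k, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            g = single_node_graph(dirs)
            m = dirs @ rng.normal(0, 0.5, size=3) + rng.normal(0, 0.1, size=k)
            proj = projection_vectors(m, g)
            upd = reconstruct_update(proj, g, eps=0.0)
            res = minimize(sphere_fit_objective, upd.centers[0] + 0.1,
                           args=(proj.v,), method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14,
                                    "maxiter": 5000})
            scale = max(1.0, np.linalg.norm(upd.centers[0]))
            assert np.linalg.norm(upd.centers[0] - res.x) / scale < 1e-6

    def test_delta_p_is_twice_center_and_A_symmetric(self, rng, random_graph):
        m = rng.normal(size=random_graph.n_edges)
        upd = reconstruct_update(projection_vectors(m, random_graph), random_graph)
        np.testing.assert_array_equal(upd.delta_p, 2.0 * upd.centers)
        np.testing.assert_allclose(upd.A, np.swapaxes(upd.A, 1, 2), atol=0)

    def test_singular_without_regularization_names_node(self):
        g = single_node_graph(np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0]]))
        proj = projection_vectors(np.zeros(3), g)
        with pytest.raises(np.linalg.LinAlgError, match="node 0"):
            reconstruct_update(proj, g, eps=0.0)
        upd = reconstruct_update(proj, g, eps=1e-6)  # resolved by eps > 0
        np.testing.assert_array_equal(upd.delta_p, 0.0)


class TestPositionalUpdateHead:
    def test_zeroed_network_keeps_positions(self, rng, random_conformation):
        g = build_graph(random_conformation, cutoff=3.5)
        head = PositionalUpdateHead(4, rng)
        for p in head.parameters():
            p.data[:] = 0.0
        node = Tensor(rng.normal(size=(g.n_nodes, 4)))
        edge = Tensor(rng.normal(size=(g.n_edges, 4)))
        new_pos, delta, m = head(node, edge, g, random_conformation.positions)
        np.testing.assert_array_equal(m.data, 0.0)
        np.testing.assert_array_equal(new_pos, random_conformation.positions)

    def test_se3_equivariance(self, rng, random_conformation):
        """Invariant features + rotated geometry ⇒ update rotates with input."""
        g = build_graph(random_conformation, cutoff=3.5)
        head = PositionalUpdateHead(4, rng)
        node = Tensor(rng.normal(size=(g.n_nodes, 4)))
        edge = Tensor(rng.normal(size=(g.n_edges, 4)))
        _, delta0, _ = head(node, edge, g, random_conformation.positions)
        R, t = random_rotation(rng), rng.normal(size=3)
        moved = Conformation(random_conformation.elements,
                             random_conformation.positions @ R.T + t)
        gm = build_graph(moved, cutoff=3.5)
        _, delta1, _ = head(node, edge, gm, moved.positions)
        np.testing.assert_allclose(delta1, delta0 @ R.T, atol=1e-6)

    def test_translation_leaves_update_unchanged(self, rng, random_conformation):
        g = build_graph(random_conformation, cutoff=3.5)
        head = PositionalUpdateHead(4, rng)
        node = Tensor(rng.normal(size=(g.n_nodes, 4)))
        edge = Tensor(rng.normal(size=(g.n_edges, 4)))
        _, delta0, _ = head(node, edge, g, random_conformation.positions)
        shifted = Conformation(random_conformation.elements,
                               random_conformation.positions + 5.0)
        gs = build_graph(shifted, cutoff=3.5)
        _, delta1, _ = head(node, edge, gs, shifted.positions)
        np.testing.assert_allclose(delta1, delta0, atol=1e-9)

    def test_nonfinite_prediction_reports_block(self, rng, random_conformation):
        g = build_graph(random_conformation, cutoff=3.5)
        head = PositionalUpdateHead(4, rng)
        head.mlp.fc2.bias.data[:] = np.inf
        node = Tensor(rng.normal(size=(g.n_nodes, 4)))
        edge = Tensor(rng.normal(size=(g.n_edges, 4)))
        with pytest.raises(FloatingPointError, match="block 3"):
            head(node, edge, g, random_conformation.positions, block_index=3)
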