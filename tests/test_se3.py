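"""Chirality vectors, torsion angles, circular harmonics, and the encoder."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omnimol.molgraph import Conformation, build_graph
from omnimol.se3 import (SE3Encoder, chirality_vectors, circular_harmonics,
                         radial_embedding, torsion_angles)
from omnimol.synthdata import make_chiral_dataset

from conftest import random_rotation


def naive_chirality_vectors(graph):
    """Direct double-loop evaluation of the cross-product sums."""
    E = graph.n_edges
    c = np.zeros((E, 3))
    for e, (i, j) in enumerate(graph.edges):
        d_ij = graph.directions[e]
        for eid in graph.edge_ids_of_node[i]:
            k = graph.edges[eid, 1]
            if k == j:
                continue
            c[e] += np.cross(d_ij, graph.directions[eid])
    return c


class TestChiralityVectors:
    def test_matches_naive_double_loop(self, rng):
        conf = Conformation([6] * 5, rng.normal(0, 1.2, (5, 3)))
        g = build_graph(conf, cutoff=5.0)
        cv = chirality_vectors(g)
        np.testing.assert_allclose(cv.c_ij, naive_chirality_vectors(g), atol=1e-12)
        np.testing.assert_allclose(cv.c_ji, cv.c_ij[g.reverse_index], atol=0)

    def test_collinear_molecule_degenerate(self):
        pos = np.array([[float(i), 0, 0] for i in range(5)])
        g = build_graph(Conformation([6] * 5, pos), cutoff=10.0)
        cv = chirality_vectors(g)
        assert cv.degenerate_mask.all()
        np.testing.assert_allclose(cv.c_ij, 0.0, atol=1e-15)

    def test_rotation_equivariance(self, random_conformation, rng):
        g = build_graph(random_conformation, cutoff=3.5)
        cv = chirality_vectors(g)
        R = random_rotation(rng)
        rot = Conformation(random_conformation.elements,
                           random_conformation.positions @ R.T)
        cv_rot = chirality_vectors(build_graph(rot, cutoff=3.5))
        np.testing.assert_allclose(cv_rot.c_ij, cv.c_ij @ R.T, atol=1e-9)


class TestTorsionAngles:
    def test_directed_pair_symmetry_exact(self, random_graph):
        """ψ_ij = ψ_ji bitwise: both directed evaluations agree."""
        tf = torsion_angles(chirality_vectors(random_graph), random_graph)
        np.testing.assert_array_equal(tf.psi, tf.psi[random_graph.reverse_index])

    def test_planar_molecule_zero_torsion(self, rng):
        xy = rng.normal(0, 1.5, size=(6, 2))
        pos = np.column_stack([xy, np.zeros(6)])
        g = build_graph(Conformation([6] * 6, pos), cutoff=6.0)
        tf = torsion_angles(chirality_vectors(g), g)
        np.testing.assert_allclose(tf.psi, 0.0, atol=1e-9)

    def test_reflection_negates_psi(self, random_conformation):
        g = build_graph(random_conformation, cutoff=3.5)
        tf = torsion_angles(chirality_vectors(g), g)
        mir = random_conformation.mirrored()
        gm = build_graph(mir, cutoff=3.5)
        tfm = torsion_angles(chirality_vectors(gm), gm)
        valid = tf.valid & tfm.valid
        assert valid.any()
        np.testing.assert_allclose(tfm.psi[valid], -tf.psi[valid], atol=1e-9)

    def test_rigid_motion_invariance(self, random_conformation, rng):
        g = build_graph(random_conformation, cutoff=3.5)
        tf = torsion_angles(chirality_vectors(g), g)
        for _ in range(10):
            R, t = random_rotation(rng), rng.normal(size=3)
            moved = Conformation(random_conformation.elements,
                                 random_conformation.positions @ R.T + t)
            gm = build_graph(moved, cutoff=3.5)
            tfm = torsion_angles(chirality_vectors(gm), gm)
            np.testing.assert_allclose(tfm.psi, tf.psi, atol=1e-9)

    def test_range_and_degenerate_handling(self, random_graph):
        tf = torsion_angles(chirality_vectors(random_graph), random_graph)
        assert (np.abs(tf.psi) <= np.pi / 2 + 1e-15).all()
        assert (tf.psi[~tf.valid] == 0.0).all()


class TestCircularHarmonics:
    def test_zero_angle(self):
        h = circular_harmonics(np.zeros(3), Omega=4)
        assert h.shape == (3, 2 * 9)
        np.testing.assert_array_equal(h[:, :9], 0.0)   # sin block
        np.testing.assert_array_equal(h[:, 9:], 1.0)   # cos block

    def test_scalar_trig_oracle(self):
        psi = np.array([np.pi / 4])
        h = circular_harmonics(psi, Omega=2)
        omegas = np.arange(-2, 3)
        np.testing.assert_allclose(h[0, :5], np.sin(omegas * np.pi / 4), atol=1e-15)
        np.testing.assert_allclose(h[0, 5:], np.cos(omegas * np.pi / 4), atol=1e-15)

    def test_reflection_negates_sine_block_only(self, rng):
        psi = rng.uniform(-np.pi / 2, np.pi / 2, size=20)
        h, hm = circular_harmonics(psi, 3), circular_harmonics(-psi, 3)
        np.testing.assert_allclose(hm[:, :7], -h[:, :7], atol=1e-15)
        np.testing.assert_allclose(hm[:, 7:], h[:, 7:], atol=1e-15)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(-np.pi / 2, np.pi / 2), st.integers(1, 6))
    def test_components_bounded(self, angle, Omega):
        h = circular_harmonics(np.array([angle]), Omega)
        assert h.shape == (1, 2 * (2 * Omega + 1))
        assert (np.abs(h) <= 1.0).all()

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError, match="Omega"):
            circular_harmonics(np.zeros(1), Omega=0)


class TestRadialEmbedding:
    def test_center_hits_one(self):
        centers = np.linspace(0.0, 4.0, 8)
        vals = radial_embedding(centers[1:], n_basis=8, r_max=4.0)
        for row, c in zip(vals, range(1, 8)):
            assert row[c] == pytest.approx(1.0)

    def test_monotone_decay_from_center(self):
        r = np.linspace(2.0, 4.0, 50)
        vals = radial_embedding(r, n_basis=8, r_max=4.0)[:, 4]  # center at 2.2857
        peak = np.argmax(vals)
        assert (np.diff(vals[: peak + 1]) >= 0).all()
        assert (np.diff(vals[peak:]) <= 0).all()

    def test_closed_form_oracle(self, rng):
        r = rng.uniform(0.5, 4.5, size=30)
        vals = radial_embedding(r, n_basis=16, r_max=5.0)
        centers = np.linspace(0, 5.0, 16)
        width = 5.0 / 15
        expected = np.exp(-0.5 * ((r[:, None] - centers) / width) ** 2)
        np.testing.assert_allclose(vals, expected, atol=1e-15)
        assert ((vals > 0) & (vals <= 1)).all()

    def test_errors(self):
        with pytest.raises(ValueError, match="r_max"):
            radial_embedding(np.ones(1), 4, r_max=0.0)
        with pytest.raises(ValueError, match="positive"):
            radial_embedding(np.array([0.0]), 4, r_max=2.0)


class TestSE3Encoder:
    def _encode(self, conf, use_torsion=True, seed=0):
        enc = SE3Encoder(16, np.random.default_rng(seed), Omega=2, n_basis=8,
                         r_max=3.5, use_torsion=use_torsion)
        g = build_graph(conf, cutoff=3.5)
        node, edge = enc(conf, g)
        return node.data, edge.data

    def test_rigid_motion_invariance(self, random_conformation, rng):
        n0, e0 = self._encode(random_conformation)
        R, t = random_rotation(rng), rng.normal(size=3)
        moved = Conformation(random_conformation.elements,
                             random_conformation.positions @ R.T + t)
        n1, e1 = self._encode(moved)
        np.testing.assert_allclose(n1, n0, atol=1e-6)
        np.testing.assert_allclose(e1, e0, atol=1e-6)

    def test_enantiomers_identical_without_torsion(self):
        mol = make_chiral_dataset(1, seed=0)[0]
        n0, e0 = self._encode(mol.conformation, use_torsion=False)
        n1, e1 = self._encode(mol.conformation.mirrored(), use_torsion=False)
        np.testing.assert_array_equal(n0, n1)  # bit-identical
        np.testing.assert_array_equal(e0, e1)

    def test_enantiomers_differ_with_torsion(self):
        mol = make_chiral_dataset(1, seed=0)[0]
        n0, e0 = self._encode(mol.conformation, use_torsion=True)
        n1, e1 = self._encode(mol.conformation.mirrored(), use_torsion=True)
        assert np.abs(e0 - e1).max() > 1e-6

    def test_unknown_element_rejected(self):
        conf = Conformation([6, 118], [[0, 0, 0], [1.5, 0, 0]])
        enc = SE3Encoder(8, np.random.default_rng(0))
        g = build_graph(conf, cutoff=3.0)
        with pytest.raises(ValueError, match="supported atomic"):
            enc(conf, g)
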