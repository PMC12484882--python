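"""Loss identities, the balancing sampler, and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omnimol._autodiff import Tensor
from omnimol.model import ModelConfig, OmniMolModel
from omnimol.synthdata import make_multitask_suite
from omnimol.training import (LossBundle, PropertyHypergraph,
                              TaskBalancedSampler, TrainConfig,
                              balanced_batch_sizes, classification_loss,
                              evaluate, forcefield_loss, inverse_zscore,
                              regression_loss, total_loss, train, zscore)


class TestForcefieldLoss:
    def test_zero_at_equilibrium(self, rng):
        P = rng.normal(size=(5, 3))
        assert forcefield_loss(P, rng.normal(size=(5, 3)), P).item() == 0.0

    def test_reference_state_cancels(self, rng):
        """The loss is identical for any choice of the penultimate state."""
        P_S, P_star = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        a = forcefield_loss(P_S, rng.normal(size=(6, 3)), P_star).item()
        b = forcefield_loss(P_S, rng.normal(size=(6, 3)), P_star).item()
        assert a == pytest.approx(b, abs=1e-12)

    def test_reduces_to_mean_absolute_deviation(self, rng):
        for _ in range(20):
            P_S, P_ref, P_star = (rng.normal(size=(4, 3)) for _ in range(3))
            val = forcefield_loss(P_S, P_ref, P_star).item()
            assert val == pytest.approx(np.abs(P_S - P_star).mean(), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            forcefield_loss(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros((4, 3)))


class TestZScore:
    def test_identity_under_standard_params(self, rng):
        y = rng.normal(size=10)
        np.testing.assert_array_equal(zscore(y, 0.0, 1.0).data, y)

    def test_inverse_roundtrip(self, rng):
        y = rng.normal(3.0, 2.0, size=10)
        back = inverse_zscore(zscore(y, 3.0, 2.0), 3.0, 2.0).data
        np.testing.assert_allclose(back, y, atol=1e-12)

    def test_batch_moments(self, rng):
        y = rng.normal(5.0, 2.5, size=500)
        z = zscore(y, y.mean(), y.std()).data
        assert abs(z.mean()) < 1e-12
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            zscore(np.zeros(2), 0.0, 0.0)


class TestRegressionLoss:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=8)
        assert regression_loss(y, y).item() == 0.0

    def test_constant_offset(self, rng):
        y = rng.normal(size=8)
        assert regression_loss(y, y + 0.7).item() == pytest.approx(0.7, abs=1e-12)

    def test_elementwise_oracle(self, rng):
        y, p = rng.normal(size=16), rng.normal(size=16)
        assert regression_loss(y, p).item() == pytest.approx(
            np.abs(y - p).mean(), abs=1e-12)


class TestClassificationLoss:
    def test_confident_correct_is_near_zero(self):
        assert classification_loss(np.ones(4), np.ones(4) * (1 - 1e-9),
                                   0.5).item() < 1e-6

    def test_balanced_ratio_is_standard_bce(self, rng):
        y = (rng.uniform(size=50) < 0.5).astype(float)
        p = rng.uniform(0.01, 0.99, size=50)
        ours = classification_loss(y, p, 0.5).item()
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
        assert ours == pytest.approx(bce, abs=1e-12)

    def test_class_weight_mass_balances(self):
        """η·1/(2η) = (1−η)·1/(2(1−η)) = 1/2 for any positive ratio."""
        for t_plus in (0.1, 0.37, 0.9):
            assert t_plus / (2 * t_plus) == pytest.approx(0.5)
            assert (1 - t_plus) / (2 * (1 - t_plus)) == pytest.approx(0.5)
            # loss at constant p weights both classes equally in expectation
            n = 10000
            y = np.concatenate([np.ones(int(n * t_plus)),
                                np.zeros(n - int(n * t_plus))])
            p = np.full(n, 0.5)
            val = classification_loss(y, p, t_plus).item()
            assert val == pytest.approx(np.log(2.0), rel=1e-3)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError, match="t_plus"):
            classification_loss(np.ones(1), np.ones(1) * 0.5, 1.0)


class TestTotalLoss:
    def test_gamma_zero_is_regression_only(self):
        assert total_loss(Tensor(2.0), Tensor(5.0), 0.0).item() == 2.0

    def test_unit_gamma_adds(self):
        assert total_loss(Tensor(1.0), Tensor(1.0), 1.0).item() == 2.0

    def test_linear_in_gamma(self):
        vals = [total_loss(Tensor(1.0), Tensor(3.0), g).item()
                for g in (0.0, 0.5, 1.0)]
        assert vals[1] - vals[0] == pytest.approx(vals[2] - vals[1], abs=1e-12)

    def test_bundle_invariant(self):
        b = LossBundle(loss_forcefield=0.2, loss_reg=1.0, loss_cls=0.5, gamma=2.0)
        assert b.loss_total == pytest.approx(b.loss_reg + b.gamma * b.loss_cls,
                                             abs=1e-9)


class TestBalancedSampler:
    def test_theta_zero_keeps_sizes(self):
        sizes = np.array([10.0, 100.0, 1000.0])
        np.testing.assert_array_equal(balanced_batch_sizes(sizes, 0.0), sizes)

    def test_theta_one_uniform(self):
        adj = balanced_batch_sizes([10, 100, 1000], 1.0)
        np.testing.assert_allclose(adj, 370.0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.0, 1.0),
           st.lists(st.integers(1, 10000), min_size=1, max_size=12))
    def test_total_budget_conserved(self, theta, sizes):
        adj = balanced_batch_sizes(sizes, theta)
        assert adj.sum() == pytest.approx(sum(sizes), rel=1e-9)

    def test_invalid_theta(self):
        with pytest.raises(ValueError, match="theta"):
            balanced_batch_sizes([1, 2], 1.5)

    def test_empirical_frequencies(self, rng):
        sizes = np.array([20, 200, 600])
        sampler = TaskBalancedSampler(sizes, 0.5, rng)
        draws = np.bincount([sampler.draw() for _ in range(10000)], minlength=3)
        probs = sampler.probs
        for k in range(3):
            se = np.sqrt(10000 * probs[k] * (1 - probs[k]))
            assert abs(draws[k] - 10000 * probs[k]) < 3 * se


class TestPropertyHypergraph:
    def test_partial_annotation_allowed(self):
        hg = PropertyHypergraph(molecules=list(range(10)), properties=[0, 1],
                                membership={0: {0, 1, 2}, 1: set(range(10))})
        assert hg.labeled_fraction(0) == pytest.approx(0.3)

    def test_membership_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            PropertyHypergraph(molecules=[0, 1], properties=[0],
                               membership={0: {5}})


@pytest.fixture(scope="module")
def tiny_suite():
    return make_multitask_suite(24, 3, coverage=0.8, seed=3, sigma=0.2)


@pytest.fixture(scope="module")
def tiny_model_cfg():
    return ModelConfig(n_layers_per_block=1, n_recycles=1, hidden_dim=16,
                       n_heads=2, n_experts=2, d_emb=8, n_basis=8, Omega=2,
                       cutoff=4.0)


class TestTrainLoop:
    def test_loss_decreases(self, tiny_suite, tiny_model_cfg):
        model = OmniMolModel(tiny_model_cfg, seed=0)
        cfg = TrainConfig(lr=2e-3, epochs=6, batch_size=8, seed=0, lambda_geo=1.0)
        log, _ = train(model, tiny_suite.dataset, cfg)
        first, last = log[0], log[-1]
        keys = [k for k in ("cls_loss", "reg_loss", "geo_loss") if k in first]
        assert sum(last[k] for k in keys) < sum(first[k] for k in keys)

    def test_zero_learning_rate_freezes_weights(self, tiny_suite, tiny_model_cfg):
        model = OmniMolModel(tiny_model_cfg, seed=0)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        cfg = TrainConfig(lr=0.0, epochs=1, batch_size=8, seed=0)
        train(model, tiny_suite.dataset, cfg)
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_resume_is_bit_identical(self, tiny_suite, tiny_model_cfg, tmp_path):
        cfg4 = TrainConfig(lr=1e-3, epochs=4, batch_size=8, seed=1, lambda_geo=0.5)
        m_straight = OmniMolModel(tiny_model_cfg, seed=0)
        log_straight, _ = train(m_straight, tiny_suite.dataset, cfg4)

        cfg2 = TrainConfig(lr=1e-3, epochs=2, batch_size=8, seed=1, lambda_geo=0.5)
        m_resumed = OmniMolModel(tiny_model_cfg, seed=0)
        _, state = train(m_resumed, tiny_suite.dataset, cfg2)
        log_resumed, _ = train(m_resumed, tiny_suite.dataset, cfg4,
                               resume_state=state)
        assert log_resumed == log_straight
        for k, v in m_resumed.state_dict().items():
            np.testing.assert_array_equal(v, m_straight.state_dict()[k])

    def test_evaluate_reports_all_tasks(self, tiny_suite, tiny_model_cfg):
        model = OmniMolModel(tiny_model_cfg, seed=0)
        metrics = evaluate(model, tiny_suite.dataset)
        assert set(metrics) == {t.task_id for t in tiny_suite.dataset.tasks}
        for tid, m in metrics.items():
            assert ("accuracy" in m) or ("mae" in m)
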