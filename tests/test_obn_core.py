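"""Attention weighting, operation loss, branch losses, and the model contract."""

import numpy as np
import pytest

from obnet.nn import Tensor
from obnet.obn_core import (BranchOutputs, ObnConfig, ObnModel, attend,
                            branch_loss, inverse_frequency_weights,
                            operation_loss, total_loss)


class TestAttend:
    def test_zero_attention_is_identity(self, rng):
        g = rng.random((2, 3, 4, 4))
        np.testing.assert_array_equal(attend(g, np.zeros((2, 1, 4, 4))), g)

    def test_full_attention_doubles(self, rng):
        g = rng.random((1, 2, 4, 4))
        np.testing.assert_allclose(attend(g, np.ones((1, 1, 4, 4))), 2 * g)

    def test_elementwise_example(self):
        g = np.array([[1.0, 2.0], [3.0, 4.0]])[None, None]
        M = np.array([[0.0, 0.5], [0.5, 1.0]])[None, None]
        np.testing.assert_allclose(attend(g, M)[0, 0],
                                   [[1.0, 3.0], [4.5, 8.0]])

    def test_linear_in_features(self, rng):
        g1, g2 = rng.random((1, 2, 3, 3)), rng.random((1, 2, 3, 3))
        M = rng.random((1, 1, 3, 3))
        np.testing.assert_allclose(attend(g1 + 2 * g2, M),
                                   attend(g1, M) + 2 * attend(g2, M), atol=1e-12)

    def test_spatial_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            attend(rng.random((1, 2, 4, 4)), rng.random((1, 1, 8, 8)))

    def test_matches_loop_oracle(self, rng):
        g = rng.random((5, 16, 16))[None]
        M = rng.random((16, 16))[None, None]
        out = attend(g, M)
        for c in range(5):
            for i in range(16):
                for j in range(16):
                    assert out[0, c, i, j] == pytest.approx(
                        (1 + M[0, 0, i, j]) * g[0, c, i, j], rel=1e-12)


class TestOperationLoss:
    def test_zero_map_is_zero(self, rng):
        W = rng.integers(0, 2, (8, 8))
        assert operation_loss(np.zeros((8, 8)), W, 0.5) == 0.0

    def test_zero_weightmap_is_zero(self, rng):
        assert operation_loss(rng.random((8, 8)), np.zeros((8, 8)), 0.1) == 0.0

    def test_worked_example_no_resize(self):
        M = np.array([[1.0, 0.0], [0.0, 1.0]])
        W = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert operation_loss(M, W, 0.1) == pytest.approx(0.1, rel=1e-12)

    def test_linear_in_lambda(self, rng):
        M, W = rng.random((4, 4)), rng.integers(0, 2, (4, 4))
        base = operation_loss(M, W, 0.01)
        for a in (2.0, 7.5):
            assert operation_loss(M, W, 0.01 * a) == pytest.approx(a * base, rel=1e-12)

    def test_quadratic_in_map_scale(self, rng):
        M, W = rng.random((6, 6)), rng.integers(0, 2, (6, 6))
        base = operation_loss(M, W, 0.1)
        for s in (0.3, 0.8):
            assert operation_loss(s * M, W, 0.1) == pytest.approx(s * s * base, rel=1e-12)

    def test_monotone_in_weight_map(self, rng):
        M = rng.random((1, 1, 4, 4))
        W1 = rng.integers(0, 2, (16, 16))
        W2 = np.maximum(W1, rng.integers(0, 2, (16, 16)))
        assert operation_loss(M, W1, 0.1) <= operation_loss(M, W2, 0.1) + 1e-15

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            operation_loss(rng.random((4, 4)), np.ones((4, 4)), -0.1)

    def test_gradient_matches_finite_differences(self, rng):
        """Analytic dL_ope/dM vs central differences on a 4x4 instance."""
        m_data = rng.random((1, 1, 4, 4))
        W = rng.integers(0, 2, (4, 4)).astype(float)
        M = Tensor(m_data.copy(), requires_grad=True)
        operation_loss(M, W, 0.1).backward()
        eps = 1e-6
        for i in range(4):
            for j in range(4):
                up, down = m_data.copy(), m_data.copy()
                up[0, 0, i, j] += eps
                down[0, 0, i, j] -= eps
                fd = (operation_loss(up, W, 0.1) - operation_loss(down, W, 0.1)) / (2 * eps)
                assert M.grad[0, 0, i, j] == pytest.approx(fd, abs=1e-4)

    def test_upsampled_path_matches_brute_force(self, rng):
        """With resize: loss equals lambda * sum((upsample(M) * W)^2)/N computed
        by an independent dense-matrix construction."""
        from obnet.nn.engine import _interp_matrix

        M = rng.random((2, 1, 4, 4))
        W = rng.integers(0, 2, (2, 12, 12)).astype(float)
        A = _interp_matrix(4, 12, np.float64)
        expected = 0.0
        for b in range(2):
            up = A @ M[b, 0] @ A.T
            expected += 0.05 * ((up * W[b]) ** 2).sum()
        expected /= 2
        assert operation_loss(M, W, 0.05) == pytest.approx(expected, rel=1e-12)


class TestBranchLoss:
    def test_inverse_ratio_weights_match_cohort_counts(self):
        """2002 normal vs 1030 abnormal gives weight ratio 2002/1030."""
        labels = np.r_[np.zeros(2002, dtype=int), np.ones(1030, dtype=int)]
        w = inverse_frequency_weights(labels, 2)
        assert w[1] / w[0] == pytest.approx(2002 / 1030, rel=1e-9)
        assert w[1] / w[0] == pytest.approx(1.9437, abs=5e-5)

    def test_uniform_counts_reduce_to_unweighted(self, rng):
        logits = Tensor(rng.normal(size=(8, 2)))
        labels = np.array([0, 1] * 4)
        w = inverse_frequency_weights(labels, 2)
        weighted = branch_loss(logits, labels, w).item()
        plain = branch_loss(logits, labels, None).item()
        assert weighted == pytest.approx(plain, rel=1e-9)

    def test_perfect_logits_drive_loss_to_zero(self):
        logits = Tensor(np.array([[30.0, -30.0], [-30.0, 30.0]]))
        assert branch_loss(logits, np.array([0, 1]), None).item() < 1e-9

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            inverse_frequency_weights(np.zeros(5, dtype=int), 2)

    def test_multilabel_is_mean_bce(self, rng):
        logits = Tensor(rng.normal(size=(4, 3)))
        y = rng.integers(0, 2, (4, 3)).astype(float)
        got = branch_loss(logits, y, multilabel=True).item()
        p = 1 / (1 + np.exp(-logits.data))
        want = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
        assert got == pytest.approx(want, rel=1e-9)


@pytest.fixture(scope="module")
def model_and_batch():
    cfg = ObnConfig(input_size=64, seed=0, lambda_=0.1)
    model = ObnModel(cfg)
    rng = np.random.default_rng(0)
    x = rng.random((3, 64, 64))
    labels = np.array([0, 1, 1])
    W = rng.integers(0, 2, (3, 64, 64)).astype(float)
    return cfg, model, x, labels, W


class TestModelAndTotalLoss:
    def test_output_shapes_and_ranges(self, model_and_batch):
        cfg, model, x, _, _ = model_and_batch
        outs = model.forward(x)
        assert outs.att_logits.shape == (3, 2)
        assert outs.per_logits.shape == (3, 2)
        assert outs.attention.shape == (3, 1, 8, 8)
        assert (outs.attention.data >= 0).all() and (outs.attention.data <= 1).all()

    def test_attention_head_is_14px_at_224(self):
        model = ObnModel(ObnConfig(input_size=224, seed=0))
        assert model.attention_side == 14

    def test_eval_forward_deterministic(self, model_and_batch):
        _, model, x, _, _ = model_and_batch
        model.eval()
        a = model.forward(x).per_logits.data
        b = model.forward(x).per_logits.data
        model.train()
        np.testing.assert_array_equal(a, b)

    def test_wrong_spatial_size_rejected(self, model_and_batch):
        _, model, _, _, _ = model_and_batch
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 32, 32)))

    def test_total_is_sum_of_components(self, model_and_batch):
        cfg, model, x, labels, W = model_and_batch
        lb = total_loss(model.forward(x), labels, W, cfg)
        parts = lb.as_floats()
        assert parts["total"] == pytest.approx(
            parts["l_att"] + parts["l_per"] + parts["l_ope"], abs=1e-9)
        assert min(parts["l_att"], parts["l_per"], parts["l_ope"]) >= 0

    def test_components_recompute_independently(self, model_and_batch):
        cfg, model, x, labels, W = model_and_batch
        outs = model.forward(x)
        lb = total_loss(outs, labels, W, cfg)
        assert lb.l_ope.item() == pytest.approx(
            operation_loss(outs.attention.data, W, cfg.lambda_), rel=1e-9)
        assert lb.l_att.item() == pytest.approx(
            branch_loss(Tensor(outs.att_logits.data), labels).item(), rel=1e-9)

    def test_lambda_zero_reduces_to_abn(self, model_and_batch):
        _, model, x, labels, W = model_and_batch
        cfg0 = ObnConfig(input_size=64, seed=0, lambda_=0.0)
        lb = total_loss(model.forward(x), labels, W, cfg0)
        assert lb.l_ope.item() == 0.0
        assert lb.total.item() == lb.l_att.item() + lb.l_per.item()

    def test_lambda_positive_requires_weight_maps(self, model_and_batch):
        cfg, model, x, labels, _ = model_and_batch
        with pytest.raises(ValueError):
            total_loss(model.forward(x), labels, None, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ObnConfig(lambda_=-1)
        with pytest.raises(ValueError):
            ObnConfig(backbone="resnet50")
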