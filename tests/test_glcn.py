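"""GLCN core: soft adjacency, regularizer, pairwise convolution, pooling.

Reference values come from closed forms and from independent pure-Python
loop implementations of each equation.
"""

import math

import numpy as np
import pytest

import glcndta as g
from glcndta.autodiff import Tensor
from glcndta.glcn import (
    GLCNLayerParams,
    _abs_dist_dot,
    _fused_pair_conv,
    _pairwise_sqdist,
    glcn_forward,
    init_glcn_params,
)

from _oracles import conv_oracle, hidden_oracle, loss_oracle


def _random_layer(rng, d):
    return GLCNLayerParams(
        w=Tensor(rng.normal(size=d), requires_grad=True),
        W_vih=Tensor(rng.normal(size=(d, d)), requires_grad=True),
        W_vjh=Tensor(rng.normal(size=(d, d)), requires_grad=True),
        b=Tensor(rng.normal(size=d), requires_grad=True),
        W=Tensor(rng.normal(size=(d, d)), requires_grad=True),
    )


# ---------------------------------------------------------------------------
# graph learning (soft adjacency)


class TestGraphLearning:
    def test_single_node_gives_trivial_adjacency(self):
        A = g.graph_learning(np.array([[1.0, 2.0]]), np.array([0.5, 0.5]))
        np.testing.assert_allclose(A.data, [[1.0]])

    def test_zero_weight_gives_uniform_rows(self):
        V = np.random.default_rng(0).normal(size=(5, 3))
        A = g.graph_learning(V, np.zeros(3))
        np.testing.assert_allclose(A.data, np.full((5, 5), 0.2))

    def test_identical_nodes_split_evenly(self):
        V = np.array([[1.0, 2.0], [1.0, 2.0]])
        A = g.graph_learning(V, np.array([3.0, -1.0]))
        np.testing.assert_allclose(A.data, np.full((2, 2), 0.5))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            g.graph_learning(np.zeros((0, 3)), np.zeros(3))

    def test_rows_are_stochastic_across_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 13))
            d = int(rng.integers(2, 17))
            A = g.graph_learning(rng.normal(size=(n, d)), rng.normal(size=d))
            assert np.all(A.data >= 0)
            np.testing.assert_allclose(A.data.sum(axis=1), 1.0, atol=1e-6)

    def test_restricting_support_masks_softmax(self, rng):
        V = rng.normal(size=(4, 3))
        allowed = np.eye(4)
        A = g.graph_learning(V, rng.normal(size=3), allowed=allowed)
        np.testing.assert_allclose(A.data, np.eye(4), atol=1e-12)


class TestGraphLearningLoss:
    def test_single_node_closed_form(self):
        # A = [[1]], zero distance: exp(1) + ||A||_F^2 = e + 1
        loss = g.graph_learning_loss([[1.0]], [[0.3, 0.7]], eta=1.0, gamma=1.0)
        assert loss.item() == pytest.approx(math.e + 1.0, abs=1e-9)

    def test_two_identical_nodes_closed_form(self):
        # all four A entries 0.5, all distances 0, gamma 0: exp(0.5)
        A = np.full((2, 2), 0.5)
        V = np.array([[1.0, 2.0], [1.0, 2.0]])
        loss = g.graph_learning_loss(A, V, eta=1.0, gamma=0.0)
        assert loss.item() == pytest.approx(math.exp(0.5), abs=1e-9)

    def test_matches_loop_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n, d = int(rng.integers(2, 6)), int(rng.integers(2, 5))
            V = rng.normal(size=(n, d))
            A = g.graph_learning(V, rng.normal(size=d)).data
            eta, gamma = rng.uniform(0, 2, size=2)
            ours = g.graph_learning_loss(A, V, eta, gamma).item()
            # 1e-10 absolute, relative when exp() pushes values past O(1)
            assert ours == pytest.approx(loss_oracle(A, V, eta, gamma), rel=1e-10, abs=1e-10)

    def test_increasing_a_distance_increases_loss(self, rng):
        V = rng.normal(size=(3, 2))
        A = g.graph_learning(V, rng.normal(size=2)).data
        base = g.graph_learning_loss(A, V, 1.0, 1.0).item()
        V2 = V.copy()
        V2[0] += 2.0  # move node 0 away from the others
        assert g.graph_learning_loss(A, V2, 1.0, 1.0).item() > base

    def test_gradients_match_finite_differences(self, rng):
        V = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        w = Tensor(rng.normal(size=3), requires_grad=True)

        def value():
            A = g.graph_learning(V, w)
            return g.graph_learning_loss(A, V, eta=1.0, gamma=1.0)

        value().backward()
        for tensor in (V, w):
            flat, grad = tensor.data.ravel(), tensor.grad.ravel()
            for idx in range(flat.size):
                h, orig = 1e-6, flat[idx]
                flat[idx] = orig + h
                up = value().item()
                flat[idx] = orig - h
                down = value().item()
                flat[idx] = orig
                fd = (up - down) / (2 * h)
                assert abs(fd - grad[idx]) / max(abs(fd), abs(grad[idx]), 1e-8) < 1e-4


# ---------------------------------------------------------------------------
# pairwise hidden features and convolution


class TestPairwiseOps:
    def test_zero_parameters_give_zero_hidden(self):
        layer = GLCNLayerParams(
            w=Tensor(np.zeros(3)),
            W_vih=Tensor(np.zeros((3, 3))),
            W_vjh=Tensor(np.zeros((3, 3))),
            b=Tensor(np.zeros(3)),
            W=Tensor(np.zeros((3, 3))),
        )
        H = g.pairwise_hidden(np.ones((4, 3)), layer)
        np.testing.assert_array_equal(H.data, 0.0)

    def test_half_identity_projections_reproduce_nodes(self):
        d = 3
        layer = GLCNLayerParams(
            w=Tensor(np.zeros(d)),
            W_vih=Tensor(0.5 * np.eye(d)),
            W_vjh=Tensor(0.5 * np.eye(d)),
            b=Tensor(np.zeros(d)),
            W=Tensor(np.eye(d)),
        )
        V = np.tile([[1.0, 2.0, 0.5]], (3, 1))  # identical nonnegative nodes
        H = g.pairwise_hidden(V, layer)
        for i in range(3):
            for j in range(3):
                np.testing.assert_allclose(H.data[i, j], V[0])

    def test_hidden_matches_loop_oracle(self, rng):
        for _ in range(50):
            n, d = int(rng.integers(2, 6)), int(rng.integers(2, 5))
            V = rng.normal(size=(n, d))
            layer = _random_layer(rng, d)
            H = g.pairwise_hidden(V, layer)
            expected = hidden_oracle(V, layer.W_vih.data, layer.W_vjh.data, layer.b.data)
            np.testing.assert_allclose(H.data, expected, atol=1e-10)

    def test_conv_zero_weight_gives_zero(self, rng):
        V = rng.normal(size=(3, 2))
        layer = _random_layer(rng, 2)
        A = g.graph_learning(V, layer.w).data
        H = g.pairwise_hidden(V, layer)
        out = g.graph_conv(A, H, np.zeros((2, 2)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_conv_single_node_identity(self):
        h = np.array([[[0.5, 1.5]]])  # (1, 1, 2), nonnegative
        out = g.graph_conv(np.array([[1.0]]), h, np.eye(2))
        np.testing.assert_allclose(out.data, [[0.5, 1.5]])

    def test_conv_matches_loop_oracle(self, rng):
        for _ in range(50):
            n, d = int(rng.integers(2, 7)), int(rng.integers(2, 5))
            V = rng.normal(size=(n, d))
            layer = _random_layer(rng, d)
            A = g.graph_learning(V, layer.w).data
            H = g.pairwise_hidden(V, layer)
            out = g.graph_conv(A, H, layer.W.data)
            np.testing.assert_allclose(
                out.data, conv_oracle(A, H.data, layer.W.data), atol=1e-10
            )

    def test_fused_kernels_equal_composed_ops(self, rng):
        for _ in range(20):
            n, d = int(rng.integers(2, 8)), int(rng.integers(2, 6))
            V = Tensor(rng.normal(size=(n, d)), requires_grad=True)
            layer = _random_layer(rng, d)
            A = g.graph_learning(V, layer.w)
            composed = g.graph_conv(A, g.pairwise_hidden(V, layer), layer.W)
            P = V @ layer.W_vih.swapaxes(-1, -2)
            Qb = V @ layer.W_vjh.swapaxes(-1, -2) + layer.b
            fused = (_fused_pair_conv(A, P, Qb) @ layer.W).relu()
            np.testing.assert_allclose(fused.data, composed.data, atol=1e-12)
            # the distance kernels too
            vi = V.data[:, None, :] - V.data[None, :, :]
            np.testing.assert_allclose(
                _abs_dist_dot(V, layer.w).data, np.abs(vi) @ layer.w.data, atol=1e-12
            )
            np.testing.assert_allclose(
                _pairwise_sqdist(V).data, (vi**2).sum(-1), atol=1e-10
            )


# ---------------------------------------------------------------------------
# stacked forward pass and pooling


class TestGlcnForward:
    def test_two_layer_stack_runs_and_is_deterministic(self, rng):
        cfg = g.GLConfig(d_model=6, n_layers=2)
        params = init_glcn_params(10, cfg, np.random.default_rng(5))
        X = rng.normal(size=(4, 10))
        V1, l1 = glcn_forward(X, params, cfg)
        V2, l2 = glcn_forward(X, params, cfg)
        np.testing.assert_array_equal(V1.data, V2.data)
        assert l1.item() == l2.item()
        assert len(params.layers) == 2

    def test_zero_conv_weights_zero_embeddings_positive_loss(self, rng):
        cfg = g.GLConfig(d_model=4, n_layers=2)
        params = init_glcn_params(6, cfg, np.random.default_rng(1))
        for layer in params.layers:
            layer.W.data[:] = 0.0
        V, loss = glcn_forward(rng.normal(size=(3, 6)), params, cfg)
        np.testing.assert_array_equal(V.data, 0.0)
        assert loss.item() > 0.0

    def test_permutation_covariance(self, rng):
        cfg = g.GLConfig(d_model=5, n_layers=2)
        params = init_glcn_params(7, cfg, np.random.default_rng(3))
        X = rng.normal(size=(6, 7))
        perm = rng.permutation(6)
        V, loss = glcn_forward(X, params, cfg)
        Vp, loss_p = glcn_forward(X[perm], params, cfg)
        np.testing.assert_allclose(Vp.data, V.data[perm], atol=1e-10)
        assert loss_p.item() == pytest.approx(loss.item(), rel=1e-12)
        for mode in ("max", "mean"):
            np.testing.assert_allclose(
                g.global_pool(Vp, mode).data, g.global_pool(V, mode).data, atol=1e-12
            )

    def test_batched_masked_forward_equals_per_graph(self, rng):
        cfg = g.GLConfig(d_model=5, n_layers=2)
        params = init_glcn_params(7, cfg, np.random.default_rng(3))
        sizes = [2, 5, 3]
        graphs = [rng.normal(size=(n, 7)) for n in sizes]
        n_max = max(sizes)
        X = np.zeros((3, n_max, 7))
        mask = np.zeros((3, n_max))
        for i, f in enumerate(graphs):
            X[i, : len(f)] = f
            mask[i, : len(f)] = 1.0
        Vb, lb = glcn_forward(X, params, cfg, mask=mask)
        pooled_b = g.global_pool(Vb, "max", mask=mask)
        for i, f in enumerate(graphs):
            Vi, li = glcn_forward(f, params, cfg)
            np.testing.assert_allclose(Vb.data[i, : len(f)], Vi.data, atol=1e-6)
            assert lb.data[i] == pytest.approx(li.item(), abs=1e-6)
            np.testing.assert_allclose(
                pooled_b.data[i], g.global_pool(Vi, "max").data, atol=1e-6
            )


class TestGlobalPool:
    def test_single_node_passthrough(self):
        v = np.array([[3.0, -1.0]])
        np.testing.assert_array_equal(g.global_pool(v, "max").data, [3.0, -1.0])

    def test_coordinatewise_max(self):
        out = g.global_pool(np.array([[1.0, 0.0], [0.0, 2.0]]), "max")
        np.testing.assert_array_equal(out.data, [1.0, 2.0])

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            g.global_pool(np.zeros((0, 3)))
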