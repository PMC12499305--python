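"""Graph construction and the attention layer: logits, softmax, forward, gradients."""

import numpy as np
import pytest

from conngat._autodiff import Tensor, grad_check
from conngat.connectivity import ConnectivityMatrix
from conngat.gat import (
    GATLayer,
    GatLayerParams,
    attention_coefficients,
    attention_logits,
    gat_layer_forward,
)
from conngat.graph import BrainGraph, build_graph, cosine_edge_weights

rng = np.random.default_rng(2)


def _complete_graph(n, features, self_loops=True):
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    return BrainGraph(n, edges, [1.0] * len(edges), features, self_loops=self_loops)


class TestBuildGraph:
    def _fc(self, v):
        return ConnectivityMatrix(values=v)

    def test_identical_profiles_rank_first(self):
        v = rng.uniform(0.1, 0.9, (5, 5))
        v = (v + v.T) / 2
        # make nodes 0 and 1 have identical diagonal-excluded profiles
        v[0, 1] = v[1, 0] = 0.0
        for k in range(2, 5):
            v[1, k] = v[k, 1] = v[0, k]
        np.fill_diagonal(v, 1.0)
        g = build_graph(self._fc(v), np.zeros((5, 1)), density=0.1)
        assert (0, 1) in g.edge_weight
        assert g.edge_weight[(0, 1)] == pytest.approx(1.0)

    def test_orthogonal_profiles_cosine_zero(self):
        sims = cosine_edge_weights(np.array([[0.0, 0, 1, 0], [0, 0, 0, 1],
                                             [1, 0, 0, 0], [0, 1, 0, 0]]))
        assert sims[0, 1] == pytest.approx(0.0)

    def test_edge_ranking_matches_dot_product_oracle(self):
        v = rng.uniform(-1, 1, (6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        g = build_graph(self._fc(v), np.zeros((6, 1)), density=0.4)
        # oracle: cosine over rows with zeroed diagonal, full enumeration
        z = v.copy()
        np.fill_diagonal(z, 0.0)
        sims = {}
        for i in range(6):
            for j in range(i + 1, 6):
                sims[(i, j)] = (z[i] @ z[j]) / (
                    np.linalg.norm(z[i]) * np.linalg.norm(z[j])
                )
        expect = set(sorted(sims, key=lambda p: -sims[p])[:6])  # ceil(0.4*15)
        assert set(g.undirected_edges) == expect

    def test_zero_norm_row_warns_and_gets_zero_similarity(self):
        v = np.eye(4)
        with pytest.warns(UserWarning, match="zero-norm"):
            sims = cosine_edge_weights(v)
        assert np.all(sims == 0)

    def test_density_out_of_range(self):
        with pytest.raises(ValueError):
            build_graph(np.eye(4), np.zeros((4, 1)), density=0.0)


class TestAttention:
    def _params(self, f=2, fp=2, seed=0):
        r = np.random.default_rng(seed)
        return GatLayerParams(W_lin=r.normal(size=(fp, f)), a_vec=r.normal(size=2 * fp))

    def test_zero_attention_vector_gives_zero_logits(self):
        g = _complete_graph(3, rng.normal(size=(3, 2)))
        p = GatLayerParams(W_lin=rng.normal(size=(2, 2)), a_vec=np.zeros(4))
        assert attention_logits(g, p, 0, 1) == 0.0

    def test_positive_preactivation_passes_through(self):
        g = _complete_graph(2, np.ones((2, 2)))
        p = GatLayerParams(W_lin=np.eye(2), a_vec=np.ones(4))
        # pre-activation = sum(h_i) + sum(h_j) = 4 > 0
        assert attention_logits(g, p, 0, 1) == pytest.approx(4.0)

    def test_hand_expanded_three_node_instance(self):
        feats = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        W = np.array([[1.0, 2.0], [0.5, -1.0]])
        a = np.array([1.0, -1.0, 0.5, 2.0])
        g = _complete_graph(3, feats)
        p = GatLayerParams(W_lin=W, a_vec=a, leaky_slope=0.2)
        # z0 = W@[1,0] = [1, .5]; z1 = W@[0,1] = [2, -1]
        # pre = 1*1 - 1*.5 + .5*2 + 2*(-1) = 1 - .5 + 1 - 2 = -0.5 -> leaky: -0.1
        assert attention_logits(g, p, 0, 1) == pytest.approx(-0.1)

    def test_non_neighbor_rejected(self):
        g = BrainGraph(3, [(0, 1)], [1.0], np.zeros((3, 2)), self_loops=False)
        p = self._params()
        with pytest.raises(ValueError, match="not in the neighborhood"):
            attention_logits(g, p, 0, 2)

    def test_singleton_neighborhood_gets_unit_coefficient(self):
        g = BrainGraph(2, [(0, 1)], [1.0], rng.normal(size=(2, 2)), self_loops=False)
        alpha = attention_coefficients(g, self._params(), 0)
        assert alpha == {1: pytest.approx(1.0)}

    def test_equal_logits_give_uniform_coefficients(self):
        g = _complete_graph(4, np.tile(rng.normal(size=(1, 2)), (4, 1)))
        alpha = attention_coefficients(g, self._params(), 0)
        assert all(v == pytest.approx(1 / 4) for v in alpha.values())

    def test_closed_form_softmax(self):
        """Logits (0, ln2, ln4) must give (1/7, 2/7, 4/7)."""
        logits = np.array([0.0, np.log(2.0), np.log(4.0)])
        ex = np.exp(logits - logits.max())
        alpha = ex / ex.sum()
        np.testing.assert_allclose(alpha, [1 / 7, 2 / 7, 4 / 7], atol=1e-12)
        # and the layer reproduces the same normalisation on crafted inputs
        t = Tensor(logits.reshape(-1, 1))
        ex_t = (t - Tensor(np.full((3, 1), logits.max()))).exp()
        alpha_t = (ex_t / ex_t.segment_sum(np.zeros(3, int), 1).gather(np.zeros(3, int))).data
        np.testing.assert_allclose(alpha_t.ravel(), [1 / 7, 2 / 7, 4 / 7], atol=1e-12)

    def test_rows_sum_to_one_on_random_graphs(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            g = _complete_graph(6, r.normal(size=(6, 3)))
            p = GatLayerParams(W_lin=r.normal(size=(4, 3)), a_vec=r.normal(size=8))
            for i in range(6):
                alpha = attention_coefficients(g, p, i)
                assert sum(alpha.values()) == pytest.approx(1.0, abs=1e-6)
                assert all(0 < v < 1 for v in alpha.values())

    def test_empty_neighborhood_mentions_self_loops(self):
        g = BrainGraph(3, [(0, 1)], [1.0], np.zeros((3, 2)), self_loops=False)
        with pytest.raises(ValueError, match="self-loops"):
            attention_coefficients(g, self._params(), 2)

    def test_very_negative_logit_barely_perturbs_others(self):
        feats = rng.normal(size=(4, 2))
        p = self._params(seed=4)
        g_small = BrainGraph(4, [(0, 1), (0, 2)], [1.0, 1.0], feats, self_loops=False)
        alpha_before = attention_coefficients(g_small, p, 0)
        feats_big = np.vstack([feats[:3], feats[3] * 0 - 50.0])  # drives logit very low
        g_big = BrainGraph(4, [(0, 1), (0, 2), (0, 3)], [1.0] * 3, feats_big,
                           self_loops=False)
        alpha_after = attention_coefficients(g_big, p, 0)
        for j in (1, 2):
            assert alpha_after[j] == pytest.approx(alpha_before[j], abs=1e-3)


class TestLayerForward:
    def test_single_neighbor_passthrough(self):
        feats = np.array([[0.5, 1.5], [2.0, 3.0]])
        g = BrainGraph(2, [(0, 1)], [1.0], feats, self_loops=False)
        p = GatLayerParams(W_lin=np.eye(2), a_vec=rng.normal(size=4))
        out = gat_layer_forward(g, p, activation="leaky_relu")
        np.testing.assert_allclose(out[0], feats[1])  # positive, slope irrelevant
        np.testing.assert_allclose(out[1], feats[0])

    def test_identical_features_on_complete_graph(self):
        x = rng.normal(size=2)
        g = _complete_graph(5, np.tile(x, (5, 1)))
        p = GatLayerParams(W_lin=rng.normal(size=(3, 2)), a_vec=rng.normal(size=6))
        out = gat_layer_forward(g, p)
        wx = p.W_lin @ x
        sig = np.where(wx > 0, wx, 0.2 * wx)
        for i in range(5):
            np.testing.assert_allclose(out[i], sig, atol=1e-12)

    def test_node_relabeling_equivariance(self):
        feats = rng.normal(size=(5, 3))
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)]
        p = GatLayerParams(W_lin=rng.normal(size=(2, 3)), a_vec=rng.normal(size=4))
        g = BrainGraph(5, edges, [1.0] * 5, feats)
        out = gat_layer_forward(g, p)
        perm = np.array([3, 0, 4, 1, 2])
        inv = np.argsort(perm)
        edges_p = [(int(inv[i]), int(inv[j])) for i, j in edges]
        g_p = BrainGraph(5, edges_p, [1.0] * 5, feats[perm])
        out_p = gat_layer_forward(g_p, p)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12)

    def test_layer_gradient_matches_finite_differences(self):
        r = np.random.default_rng(7)
        layer = GATLayer(3, 2, rng=r)
        feats = Tensor(r.normal(size=(4, 3)))
        g = _complete_graph(4, feats.data)
        dst, src = g.directed_edge_arrays()

        def loss():
            out, alpha, _ = layer.forward(feats, dst, src, 4)
            return (out * out).sum() + (alpha * alpha).sum()

        assert grad_check(loss, layer.params) < 1e-5

    def test_uniform_mode_ignores_attention_parameters(self):
        r = np.random.default_rng(8)
        layer = GATLayer(2, 2, mode="uniform", rng=r)
        feats = Tensor(r.normal(size=(3, 2)))
        g = _complete_graph(3, feats.data)
        dst, src = g.directed_edge_arrays()
        _, alpha, _ = layer.forward(feats, dst, src, 3)
        np.testing.assert_allclose(alpha.data, 1 / 3)
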