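"""The full predictor: losses, forward semantics, training behavior."""

import numpy as np
import pytest

from conngat._autodiff import Tensor, grad_check
from conngat.graph import BrainGraph
from conngat.model import (
    ConnectomeGATRegressor,
    combined_loss,
    prediction_loss,
    smoothness_penalty,
)

rng = np.random.default_rng(4)


class TestSmoothness:
    def _two_node_graph(self):
        return BrainGraph(2, [(0, 1)], [1.0], np.zeros((2, 1)), self_loops=False)

    def test_constant_embeddings_give_zero(self):
        g = self._two_node_graph()
        att = {0: {1: 1.0}, 1: {0: 1.0}}
        assert smoothness_penalty(np.ones((2, 3)), g, att) == 0.0

    def test_two_node_hand_sum(self):
        g = self._two_node_graph()
        att = {0: {1: 1.0}, 1: {0: 1.0}}
        h = np.array([[0.0], [1.0]])
        assert smoothness_penalty(h, g, att) == pytest.approx(2.0)

    def test_quadratic_homogeneity(self):
        g = self._two_node_graph()
        att = {0: {1: 0.7}, 1: {0: 0.3}}
        h = rng.normal(size=(2, 4))
        base = smoothness_penalty(h, g, att)
        assert smoothness_penalty(2 * h, g, att) == pytest.approx(4 * base)


class TestPredictionLoss:
    def test_perfect_fit(self):
        assert prediction_loss([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_residuals(self):
        assert prediction_loss([11.0, 9.0], [10.0, 10.0]) == pytest.approx(1.0)

    def test_hand_computed_mean(self):
        assert prediction_loss([3.0, 4.0], [0.0, 0.0]) == pytest.approx(12.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prediction_loss([], [])


class TestCombinedLoss:
    def _pieces(self):
        W = rng.uniform(0, 1, (4, 2))
        H = [rng.uniform(0, 1, (2, 4))]
        X = [rng.uniform(0, 1, (4, 4))]
        g = BrainGraph(4, [(0, 1), (1, 2)], [1.0, 1.0], np.zeros((4, 1)),
                       self_loops=False)
        att = {0: {1: 1.0}, 1: {0: 0.5, 2: 0.5}, 2: {1: 1.0}, 3: {}}
        emb = rng.normal(size=(4, 3))
        return X, W, H, emb, g, att

    def test_degenerate_weights_reduce_to_reconstruction(self):
        X, W, H, emb, g, att = self._pieces()
        total, comp = combined_loss(X, W, H, emb, g, att, [1.0], [1.0], 0.1, 0.0, 0.0)
        assert total == pytest.approx(comp["reconstruction"])

    def test_global_optimum_is_zero(self):
        W = rng.uniform(0, 1, (4, 2))
        H = [rng.uniform(0, 1, (2, 4))]
        X = [W @ H[0]]
        g = BrainGraph(4, [(0, 1)], [1.0], np.zeros((4, 1)), self_loops=False)
        att = {0: {1: 1.0}, 1: {0: 1.0}}
        total, _ = combined_loss(X, W, H, np.ones((4, 2)), g, att,
                                 [5.0], [5.0], 0.0, 1.0, 1.0)
        assert total == pytest.approx(0.0)

    def test_total_is_sum_of_components(self):
        X, W, H, emb, g, att = self._pieces()
        lam, mu = 0.3, 2.0
        total, comp = combined_loss(X, W, H, emb, g, att, [1.0, 3.0], [2.0, 2.5],
                                    0.1, lam, mu)
        expect = (comp["reconstruction"] + lam * comp["smoothness"]
                  + mu * comp["prediction"])
        assert total == pytest.approx(expect, abs=1e-10)


class TestForwardSemantics:
    def test_zero_parameters_predict_final_bias(self, tiny_data, tiny_model):
        import copy

        est = copy.deepcopy(tiny_model)
        for p in est.parameters_:
            p.data = np.zeros_like(p.data)
        est.head_["b2"].data = np.full((1, 1), 7.25)
        preds = est.predict(tiny_data, idx=[0, 3])
        np.testing.assert_allclose(preds, 7.25)

    def test_duplicated_subject_identical_prediction(self, tiny_data, tiny_model):
        p = tiny_model.predict(tiny_data, idx=[2, 2])
        assert p[0] == p[1]

    def test_batch_invariance_and_order_equivariance(self, tiny_data, tiny_model):
        full = tiny_model.predict(tiny_data, idx=[0, 1, 2, 3])
        single = tiny_model.predict(tiny_data, idx=[2])
        assert single[0] == pytest.approx(full[2], abs=1e-9)
        perm = tiny_model.predict(tiny_data, idx=[3, 1, 0, 2])
        np.testing.assert_allclose(perm, full[[3, 1, 0, 2]])

    def test_empty_prediction_list(self, tiny_data, tiny_model):
        assert tiny_model.predict(tiny_data, idx=[]).size == 0

    def test_fixture_matches_layer_by_layer_trace(self, tiny_data, tiny_model):
        """Recompute one subject's prediction with explicit numpy algebra."""
        est = tiny_model
        data = tiny_data
        s = data.subjects[0]
        embeddings = []
        for bi, bname in enumerate(est._branch_names_):
            feats = est._subject_features(data, s)[bi] / est._feature_scale_[bname]
            dst, src = est._edges_for(bname, s)
            h = feats
            for layer in est.layers_[bname]:
                z = h @ layer.W.data
                pre = (z[dst] @ layer.a_self.data + z[src] @ layer.a_nbr.data)
                logit = np.where(pre > 0, pre, 0.2 * pre).ravel()
                out = np.zeros((feats.shape[0], z.shape[1]))
                for i in np.unique(dst):
                    sel = dst == i
                    ex = np.exp(logit[sel] - logit[sel].max())
                    alpha = ex / ex.sum()
                    out[i] = alpha @ z[src[sel]]
                h = np.where(out > 0, out, 0.2 * out)
            embeddings.append(h.reshape(1, -1))
        merged = np.concatenate(embeddings, axis=1)
        merged = np.where(merged > 0, merged, 0.2 * merged)
        z1 = merged @ est.head_["W1"].data + est.head_["b1"].data
        z1 = np.where(z1 > 0, z1, 0.2 * z1)
        expect = float((z1 @ est.head_["W2"].data + est.head_["b2"].data)[0, 0])
        got = float(est.predict(data, idx=[0])[0])
        assert got == pytest.approx(expect, abs=1e-9)


class TestTraining:
    def test_learning_reduces_training_mse(self, tiny_data):
        est = ConnectomeGATRegressor(
            rank=3, nmf_iters=60, epochs=60, learning_rate=3e-3, weight_decay=0.0,
            hidden_dim=4, head_hidden=12, seed=1,
        ).fit(tiny_data, train_idx=np.arange(8))
        hist = est.loss_history_
        assert hist[-1]["prediction"] < hist[0]["prediction"]
        assert hist[-1]["total"] == pytest.approx(
            hist[-1]["reconstruction"]
            + est.lambda_smooth * hist[-1]["smoothness"]
            + est.mu_pred * hist[-1]["prediction"]
        )

    def test_mu_zero_removes_prediction_pressure(self, tiny_data):
        est = ConnectomeGATRegressor(
            rank=3, nmf_iters=60, epochs=60, learning_rate=3e-3, weight_decay=0.0,
            hidden_dim=4, head_hidden=12, mu_pred=0.0, seed=1,
        ).fit(tiny_data, train_idx=np.arange(8))
        hist = est.loss_history_
        # without the prediction term the MSE does not systematically improve
        assert hist[-1]["prediction"] > 0.5 * hist[0]["prediction"]

    def test_smoothness_only_training_reduces_dispersion(self, tiny_data):
        finals, initials = [], []
        for seed in range(3):
            est = ConnectomeGATRegressor(
                rank=3, nmf_iters=60, epochs=50, learning_rate=3e-3,
                weight_decay=0.0, hidden_dim=4, head_hidden=12,
                mu_pred=0.0, lambda_smooth=1.0, seed=seed,
            ).fit(tiny_data, train_idx=np.arange(8))
            initials.append(est.loss_history_[0]["smoothness"])
            finals.append(est.loss_history_[-1]["smoothness"])
        assert np.mean(finals) < np.mean(initials)

    def test_same_seed_identical_history(self, tiny_data):
        kw = dict(rank=3, nmf_iters=40, epochs=15, learning_rate=1e-3,
                  weight_decay=0.0, hidden_dim=3, head_hidden=8, seed=11)
        a = ConnectomeGATRegressor(**kw).fit(tiny_data, train_idx=np.arange(8))
        b = ConnectomeGATRegressor(**kw).fit(tiny_data, train_idx=np.arange(8))
        assert a.loss_history_ == b.loss_history_

    def test_empty_training_split_rejected(self, tiny_data):
        with pytest.raises(ValueError, match="empty training split"):
            ConnectomeGATRegressor(epochs=1).fit(tiny_data, train_idx=[])

    def test_combined_loss_gradient_matches_finite_differences(self, tiny_data):
        """Autodiff gradients of lambda*smoothness + mu*MSE w.r.t. every
        parameter tensor agree with central differences on an 8-node fixture."""
        from conngat.synthetic import SyntheticSpec, cohort_to_dataset, generate_cohort

        spec = SyntheticSpec(n_subjects=4, n_rois=8, n_tasks=2, rank=2,
                             effect_factors=(1,), timepoints=30, seed=3)
        data = cohort_to_dataset(generate_cohort(spec))
        est = ConnectomeGATRegressor(
            rank=2, nmf_iters=50, epochs=1, learning_rate=1e-9, weight_decay=0.0,
            hidden_dim=3, head_hidden=5, seed=2,
        ).fit(data, train_idx=np.arange(4))
        y_t = Tensor(data.ages.reshape(-1, 1))

        def loss():
            pred, smooth = est._forward(data, data.subjects)
            resid = pred - y_t
            return est.mu_pred * (resid * resid).mean() + est.lambda_smooth * smooth

        assert grad_check(loss, est.parameters_) < 1e-4


class TestTopologyVariants:
    def test_subject_topology_trains_and_predicts(self, tiny_data):
        est = ConnectomeGATRegressor(
            rank=3, nmf_iters=40, epochs=10, learning_rate=1e-3, weight_decay=0.0,
            hidden_dim=3, head_hidden=8, topology="subject", seed=0,
        ).fit(tiny_data, train_idx=np.arange(8))
        assert est.predict(tiny_data, idx=[8, 9]).shape == (2,)

    def test_weighted_logits_variant_changes_predictions(self, tiny_data):
        kw = dict(rank=3, nmf_iters=40, epochs=10, learning_rate=1e-3,
                  weight_decay=0.0, hidden_dim=3, head_hidden=8, seed=0)
        plain = ConnectomeGATRegressor(**kw).fit(tiny_data, train_idx=np.arange(8))
        weighted = ConnectomeGATRegressor(weighted_logits=True, **kw).fit(
            tiny_data, train_idx=np.arange(8))
        a = plain.predict(tiny_data, idx=[8, 9])
        b = weighted.predict(tiny_data, idx=[8, 9])
        assert np.isfinite(b).all()
        assert not np.allclose(a, b)

    def test_concat_branch_mode(self, tiny_data):
        est = ConnectomeGATRegressor(
            rank=3, nmf_iters=40, epochs=10, learning_rate=1e-3, weight_decay=0.0,
            hidden_dim=3, head_hidden=8, branch_mode="concat", seed=0,
        ).fit(tiny_data, train_idx=np.arange(8))
        assert len(est._branch_names_) == 1
        assert np.isfinite(est.predict(tiny_data)).all()
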