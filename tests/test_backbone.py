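import numpy as np
import pytest

from graphema.backbone import (Backbone, BackboneConfig, GraphData,
                               inverse_frequency_weights, load_checkpoint,
                               predict, save_checkpoint, weighted_l1_loss)
from graphema.nn import (AutoClip, GlobalAttentionPool, MetaLayer, Tensor,
                         TopKPool, TransformerConv)


def random_graph(n=12, e=30, node_dim=83, edge_dim=10, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, node_dim))
    pairs = rng.integers(0, n, (e, 2))
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    edge_index = np.hstack([pairs.T, pairs.T[::-1]])
    edge_attr = rng.standard_normal((edge_index.shape[1], edge_dim))
    return GraphData(x=x, edge_index=edge_index, edge_attr=edge_attr)


def permute_graph(g, perm):
    inv = np.argsort(perm)
    return GraphData(x=g.x[perm], edge_index=inv[g.edge_index],
                     edge_attr=g.edge_attr.copy())


class TestTransformerConv:
    def test_isolated_node_depends_only_on_itself(self):
        rng = np.random.default_rng(1)
        conv = TransformerConv(8, 8, 4, 2, rng)
        x = rng.standard_normal((3, 8))
        # node 2 is isolated
        ei = np.array([[0, 1], [1, 0]])
        ea = rng.standard_normal((2, 4))
        out1 = conv(Tensor(x), ei, Tensor(ea)).data
        x2 = x.copy()
        x2[:2] += 1.0  # perturb only the connected nodes
        out2 = conv(Tensor(x2), ei, Tensor(ea)).data
        assert np.allclose(out1[2], out2[2])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        conv = TransformerConv(6, 8, 3, 2, rng)
        g = random_graph(10, 25, node_dim=6, edge_dim=3, seed=3)
        perm = np.random.default_rng(4).permutation(10)
        out = conv(Tensor(g.x), g.edge_index, Tensor(g.edge_attr)).data
        gp = permute_graph(g, perm)
        out_p = conv(Tensor(gp.x), gp.edge_index, Tensor(gp.edge_attr)).data
        assert np.allclose(out[perm], out_p, atol=1e-10)


class TestMetaLayer:
    def test_empty_edge_aggregation_is_zero(self):
        rng = np.random.default_rng(5)
        meta = MetaLayer(6, 3, 4, 8, rng)
        x = rng.standard_normal((4, 6))
        u = rng.standard_normal((1, 4))
        ei = np.zeros((2, 0), dtype=int)
        ea = Tensor(np.zeros((0, 3)))
        x_out, e_out, u_out = meta(Tensor(x), ei, ea, Tensor(u))
        assert x_out.shape == (4, 8) and e_out.shape[0] == 0
        assert np.all(np.isfinite(u_out.data))

    def test_global_output_permutation_invariant(self):
        rng = np.random.default_rng(6)
        meta = MetaLayer(6, 3, 4, 8, rng)
        g = random_graph(9, 20, node_dim=6, edge_dim=3, seed=7)
        u = Tensor(np.zeros((1, 4)))
        perm = np.random.default_rng(8).permutation(9)
        _, _, u1 = meta(Tensor(g.x), g.edge_index, Tensor(g.edge_attr), u)
        gp = permute_graph(g, perm)
        # mean aggregation over edges is order-independent; node means match
        _, _, u2 = meta(Tensor(gp.x), gp.edge_index, Tensor(gp.edge_attr), u)
        assert np.allclose(u1.data, u2.data, atol=1e-10)


class TestTopKPool:
    def test_ratio_one_keeps_all(self):
        rng = np.random.default_rng(9)
        pool = TopKPool(5, 1.0, rng)
        g = random_graph(7, 12, node_dim=5, edge_dim=2, seed=10)
        x_out, ei, ea, keep = pool(Tensor(g.x), g.edge_index, Tensor(g.edge_attr))
        assert x_out.shape[0] == 7 and len(keep) == 7

    def test_ceil_rule(self):
        rng = np.random.default_rng(11)
        pool = TopKPool(5, 0.5, rng)
        g = random_graph(10, 15, node_dim=5, edge_dim=2, seed=12)
        x_out, *_ = pool(Tensor(g.x), g.edge_index, Tensor(g.edge_attr))
        assert x_out.shape[0] == 5

    def test_tie_break_prefers_lower_index(self):
        rng = np.random.default_rng(13)
        pool = TopKPool(4, 0.5, rng)
        x = np.tile(np.ones(4), (4, 1))  # identical scores everywhere
        ei = np.zeros((2, 0), dtype=int)
        ea = Tensor(np.zeros((0, 2)))
        _, _, _, keep = pool(Tensor(x), ei, ea)
        assert keep.tolist() == [0, 1]

    def test_always_keeps_at_least_one(self):
        rng = np.random.default_rng(14)
        pool = TopKPool(3, 0.01, rng)
        g = random_graph(4, 6, node_dim=3, edge_dim=2, seed=15)
        x_out, *_ = pool(Tensor(g.x), g.edge_index, Tensor(g.edge_attr))
        assert x_out.shape[0] == 1


class TestGlobalAttentionPool:
    def test_single_node_returns_transformed_features(self):
        rng = np.random.default_rng(16)
        pool = GlobalAttentionPool(5, rng)
        x = rng.standard_normal((1, 5))
        out = pool(Tensor(x)).data
        expected = pool.feat_nn(Tensor(x)).data
        assert np.allclose(out, expected)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(17)
        pool = GlobalAttentionPool(5, rng)
        x = rng.standard_normal((8, 5))
        perm = np.random.default_rng(18).permutation(8)
        assert np.allclose(pool(Tensor(x)).data, pool(Tensor(x[perm])).data)


class TestBackboneEndToEnd:
    @pytest.mark.parametrize("variant", ["transformer", "metalayer"])
    def test_prediction_in_unit_interval(self, variant, dimer_graph_data):
        bb = Backbone(BackboneConfig(variant=variant, hidden=16, heads=4,
                                     n_layers=2, seed=1))
        score, emb = predict(bb, dimer_graph_data)
        assert 0.0 < score < 1.0
        assert np.all(np.isfinite(emb))

    @pytest.mark.parametrize("variant", ["transformer", "metalayer"])
    def test_eval_mode_deterministic(self, variant, dimer_graph_data):
        bb = Backbone(BackboneConfig(variant=variant, hidden=16, n_layers=1,
                                     dropout=0.3, seed=2))
        s1, e1 = predict(bb, dimer_graph_data)
        s2, e2 = predict(bb, dimer_graph_data)
        assert s1 == s2 and np.array_equal(e1, e2)

    @pytest.mark.parametrize("variant", ["transformer", "metalayer"])
    def test_permutation_invariance_end_to_end(self, variant):
        bb = Backbone(BackboneConfig(variant=variant, hidden=16, n_layers=2,
                                     node_dim=7, edge_dim=10, seed=3))
        g = random_graph(14, 40, node_dim=7, edge_dim=10, seed=4)
        perm = np.random.default_rng(5).permutation(14)
        s1, _ = predict(bb, g)
        s2, _ = predict(bb, permute_graph(g, perm))
        assert abs(s1 - s2) < 1e-9

    def test_checkpoint_roundtrip(self, tmp_path, dimer_graph_data):
        bb = Backbone(BackboneConfig(hidden=16, n_layers=1, seed=6))
        save_checkpoint(bb, tmp_path / "bb.json")
        bb2 = load_checkpoint(tmp_path / "bb.json")
        s1, e1 = predict(bb, dimer_graph_data)
        s2, e2 = predict(bb2, dimer_graph_data)
        assert s1 == s2
        assert np.array_equal(e1, e2)


class TestWeightedL1:
    def test_unit_weights_reduce_to_mae(self):
        pred = Tensor(np.array([0.2, 0.8, 0.5]))
        got = weighted_l1_loss(pred, np.array([0.1, 0.6, 0.9]), np.ones(3))
        assert got.item() == pytest.approx((0.1 + 0.2 + 0.4) / 3)

    def test_perfect_prediction_is_zero(self):
        pred = Tensor(np.array([0.3, 0.7]))
        assert weighted_l1_loss(pred, np.array([0.3, 0.7]),
                                np.ones(2)).item() == 0.0

    def test_zero_weight_drops_residual(self):
        pred = Tensor(np.array([0.1, 0.0]))
        got = weighted_l1_loss(pred, np.array([0.0, 0.9]),
                               np.array([2.0, 0.0]))
        assert got.item() == pytest.approx(0.1)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_l1_loss(Tensor(np.zeros(2)), np.zeros(2), np.zeros(2))

    def test_inverse_frequency_upweights_rare_bins(self):
        labels = np.array([0.05] * 9 + [0.95])
        w = inverse_frequency_weights(labels)
        assert w[-1] > w[0]


class TestAutoClip:
    def test_constant_history_threshold(self):
        clip = AutoClip(10.0)
        for _ in range(5):
            thr = clip.threshold(3.0)
        assert thr == pytest.approx(3.0)

    def test_percentile_linear_interpolation(self):
        clip = AutoClip(10.0)
        for v in range(1, 100):
            clip.threshold(float(v))
        assert clip.threshold(100.0) == pytest.approx(10.9)

    def test_clipped_norm_below_threshold(self):
        from graphema.nn import global_grad_norm
        clip = AutoClip(10.0)
        p = Tensor(np.zeros(4), requires_grad=True)
        p.grad = np.full(4, 1.0)
        clip.threshold(0.5)  # seed history low
        thr = clip([p])
        assert thr < 2.0  # clipping engaged
        assert global_grad_norm([p]) <= thr + 1e-12
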