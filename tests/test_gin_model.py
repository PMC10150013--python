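"""GIN layer arithmetic, readout invariance, the joint loss, training."""

import math

import numpy as np
import pytest

from corticograph.gin_model import (
    GINClassifier, GINConfig, gin_layer, joint_loss, predict_sequence,
    sum_readout,
)
from corticograph.graphs import ChannelGraph, N_SUBACTIONS, decode_label


def _random_graph(rng, movement="push", position=0, n_nodes=40, n_edges=60):
    pairs = rng.choice(n_nodes * (n_nodes - 1) // 2, size=n_edges,
                       replace=False)
    iu, ju = np.triu_indices(n_nodes, k=1)
    edges = np.stack([iu[pairs], ju[pairs]], axis=1)
    return ChannelGraph(
        node_features=rng.standard_normal((n_nodes, 7)),
        edges=edges, movement=movement, position=position,
        subject_id="S", group="healthy",
    )


def _labeled_set(rng, per_class=2):
    graphs = []
    for c in range(N_SUBACTIONS):
        movement, position = decode_label(c)
        for _ in range(per_class):
            graphs.append(_random_graph(rng, movement, position))
    return graphs


def _permute_graph(g, perm):
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return ChannelGraph(
        node_features=g.node_features[perm],
        edges=inv[g.edges], movement=g.movement, position=g.position,
        subject_id=g.subject_id, group=g.group,
    )


class TestGinLayer:
    def test_hand_computed_path_graph(self):
        # path 0-1-2, features [1,2,3], eps=0, identity MLP:
        # node 0: 1+2=3, node 1: 2+1+3=6, node 2: 3+2=5
        out = gin_layer([1.0, 2.0, 3.0], [[0, 1], [1, 2]], epsilon=0.0)
        assert out.tolist() == [3.0, 6.0, 5.0]

    def test_no_edges_identity(self):
        x = np.arange(12.0).reshape(4, 3)
        out = gin_layer(x, np.zeros((0, 2)), epsilon=0.0)
        assert np.array_equal(out, x)

    def test_epsilon_scales_self_contribution(self):
        out = gin_layer([1.0, 2.0], [[0, 1]], epsilon=0.5)
        assert out.tolist() == [1.5 * 1 + 2, 1.5 * 2 + 1]

    def test_permutation_equivariance(self, rng):
        x = rng.standard_normal((6, 4))
        edges = np.array([[0, 1], [1, 2], [3, 5]])
        perm = rng.permutation(6)
        inv = np.empty(6, dtype=int)
        inv[perm] = np.arange(6)
        out = gin_layer(x, edges, epsilon=0.3)
        out_perm = gin_layer(x[perm], inv[edges], epsilon=0.3)
        assert np.allclose(out[perm], out_perm)

    def test_bad_edge_rejected(self):
        with pytest.raises(ValueError, match="nonexistent"):
            gin_layer([1.0, 2.0], [[0, 5]])


class TestReadout:
    def test_hand_sum_k0(self):
        emb = [np.array([[1.0, 0.0], [0.0, 2.0]])]
        assert sum_readout(emb).tolist() == [1.0, 2.0]

    def test_permutation_invariance(self, rng):
        embs = [rng.standard_normal((5, 3)) for _ in range(3)]
        maps = [rng.standard_normal((3, 4)) for _ in range(3)]
        perm = rng.permutation(5)
        a = sum_readout(embs, maps)
        b = sum_readout([e[perm] for e in embs], maps)
        assert np.allclose(a, b)

    def test_concatenation_length(self, rng):
        embs = [rng.standard_normal((5, 3)) for _ in range(4)]
        maps = [rng.standard_normal((3, 8)) for _ in range(4)]
        assert sum_readout(embs, maps).shape == (4 * 8,)

    def test_missing_linear_map_rejected(self, rng):
        with pytest.raises(ValueError, match="missing"):
            sum_readout([np.ones((2, 3))] * 2, [np.eye(3)])


class TestJointLoss:
    def test_uniform_logits_closed_form(self):
        logits = np.zeros((4, 12))
        labels = np.array([0, 3, 7, 11])
        assert joint_loss(logits, labels, weight=1.0) == pytest.approx(
            math.log(12) + math.log(2), abs=1e-9)
        assert joint_loss(logits, labels, weight=0.5) == pytest.approx(
            math.log(12) + 0.5 * math.log(2), abs=1e-9)

    def test_confident_correct_prediction_near_zero(self):
        logits = np.full((1, 12), -50.0)
        logits[0, 4] = 50.0
        assert joint_loss(logits, [4]) < 1e-6

    def test_right_movement_wrong_position(self):
        # all mass on class 1 (push, pos 1) when truth is class 0 (push, 0):
        # the movement term vanishes, the sub-action term stays large
        logits = np.full((1, 12), -50.0)
        logits[0, 1] = 50.0
        w1 = joint_loss(logits, [0], weight=1.0)
        w0 = joint_loss(logits, [0], weight=0.0)
        assert w1 == pytest.approx(w0, abs=1e-6)  # movement CE ~ 0
        assert w0 > 10

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            joint_loss(np.zeros((1, 12)), [12])


class TestForward:
    def test_logit_shape_and_softmax(self, rng):
        model = GINClassifier(GINConfig(seed=0, epochs=1))
        graphs = [_random_graph(rng) for _ in range(3)]
        logits = model.predict_logits(graphs)
        assert logits.shape == (3, 12)
        assert np.isfinite(logits).all()
        p = np.exp(logits - logits.max(1, keepdims=True))
        p /= p.sum(1, keepdims=True)
        assert np.allclose(p.sum(1), 1.0, atol=1e-6)

    def test_isomorphic_graphs_identical_logits(self, rng):
        model = GINClassifier(GINConfig(seed=0))
        g = _random_graph(rng)
        gp = _permute_graph(g, rng.permutation(40))
        a = model.predict_logits([g])
        b = model.predict_logits([gp])
        assert np.allclose(a, b, atol=1e-9)

    def test_eval_mode_deterministic(self, rng):
        model = GINClassifier(GINConfig(seed=0))
        g = _random_graph(rng)
        a = model.predict_logits([g])
        b = model.predict_logits([g])
        assert np.array_equal(a, b)

    def test_wrong_feature_width_rejected(self, rng):
        model = GINClassifier(GINConfig(seed=0))
        g = _random_graph(rng)
        g.node_features = g.node_features[:, :5]
        with pytest.raises(ValueError):
            model.predict_logits([g])

    def test_marginalized_movement_probabilities_sum_to_one(self, rng):
        model = GINClassifier(GINConfig(seed=1))
        logits = model.predict_logits([_random_graph(rng)])
        p = np.exp(logits[0] - logits[0].max())
        p /= p.sum()
        q = p.reshape(2, 6).sum(axis=1)
        assert q.sum() == pytest.approx(1.0, abs=1e-9)


def test_analytic_gradients_match_finite_differences(rng):
    """Backprop through the whole network vs central finite differences."""
    cfg = GINConfig(num_layers=2, hidden=5, seed=3, epochs=1, batch_size=4)
    model = GINClassifier(cfg)
    graphs = [_random_graph(rng, *decode_label(c)[:2], n_nodes=6, n_edges=4)
              for c in range(4)]
    feats, a, labels, n_nodes = model._batch(graphs)

    def loss_value():
        logits, _ = model._forward(feats, a, n_nodes, training=True)
        from corticograph.gin_model import _loss_grad
        return _loss_grad(logits, labels, 1.0)[0]

    from corticograph.gin_model import _loss_grad
    logits, fw = model._forward(feats, a, n_nodes, training=True)
    _, dlogits = _loss_grad(logits, labels, 1.0)
    grads = model._backward(dlogits, fw)

    h = 1e-6
    for name in ["l1_W1", "l1_eps", "l2_gamma", "r0_W", "cls_W", "l2_b2"]:
        param = model.params[name]
        flat_idx = [0, param.size // 2, param.size - 1]
        for fi in set(flat_idx):
            orig = param.flat[fi]
            param.flat[fi] = orig + h
            lp = loss_value()
            param.flat[fi] = orig - h
            lm = loss_value()
            param.flat[fi] = orig
            numeric = (lp - lm) / (2 * h)
            assert grads[name].flat[fi] == pytest.approx(
                numeric, rel=1e-3, abs=1e-6), name


class TestTraining:
    def test_loss_decreases(self, rng):
        graphs = _labeled_set(rng, per_class=2)
        model = GINClassifier(GINConfig(epochs=50, seed=0)).fit(graphs)
        assert model.history[49]["loss"] < model.history[0]["loss"]

    def test_overfits_small_set(self, rng):
        """Capacity sanity: >= 99% training accuracy on 24 graphs."""
        graphs = _labeled_set(rng, per_class=2)
        model = GINClassifier(GINConfig(epochs=300, seed=0)).fit(graphs)
        acc = (model.predict(graphs) == [g.subaction_class for g in graphs]).mean()
        assert acc >= 0.99

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GINClassifier().fit([])

    def test_seeded_training_reproducible(self, rng):
        graphs = _labeled_set(rng, per_class=1)
        a = GINClassifier(GINConfig(epochs=5, seed=7)).fit(graphs)
        b = GINClassifier(GINConfig(epochs=7, seed=7))
        b.config.epochs = 5
        b.fit(graphs)
        assert np.array_equal(a.predict_logits(graphs), b.predict_logits(graphs))

    def test_parameter_count_independent_of_edges(self, rng):
        m1 = GINClassifier(GINConfig(seed=0))
        n_params = sum(p.size for p in m1.params.values())
        m1.fit([_random_graph(rng, n_edges=10)])
        assert sum(p.size for p in m1.params.values()) == n_params


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        graphs = _labeled_set(rng, per_class=1)
        model = GINClassifier(GINConfig(epochs=3, seed=0)).fit(graphs)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = GINClassifier.load(path)
        assert np.array_equal(model.predict_logits(graphs),
                              loaded.predict_logits(graphs))


class TestPredictSequence:
    def test_sequence_length_and_determinism(self, rng):
        model = GINClassifier(GINConfig(seed=0))
        graphs = [_random_graph(rng, "push", pos) for pos in range(6)]
        seq = predict_sequence(model, graphs)
        assert len(seq) == 6
        assert seq == predict_sequence(model, graphs)
        assert all(m in ("push", "pull") and 0 <= p < 6 for m, p in seq)

    def test_wrong_segment_count_rejected(self, rng):
        model = GINClassifier(GINConfig(seed=0))
        with pytest.raises(ValueError, match="segment"):
            predict_sequence(model, [_random_graph(rng)] * 4)

    def test_graphs_sorted_by_position(self, rng):
        model = GINClassifier(GINConfig(seed=0))
        graphs = [_random_graph(rng, "push", pos) for pos in range(6)]
        seq_fwd = predict_sequence(model, graphs)
        seq_rev = predict_sequence(model, graphs[::-1])
        assert seq_fwd == seq_rev
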