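"""Surrogate model: forward pieces, weight census, training mechanics."""

import numpy as np
import pytest

import mapent as me
from mapent.protein_graph import ProteinGraph
from mapent.surrogate import (
    SurrogateConfig,
    SurrogateModel,
    TrainResult,
    count_weights,
    embed_vertices,
    evaluate,
    gin_layer,
    predict,
    predict_batch,
    readout,
    train,
)


def graph_from(features, edges, weights, cutoff=1.0):
    return ProteinGraph(
        features=np.asarray(features, dtype=np.int8),
        edges=np.asarray(edges, dtype=int).reshape(-1, 2),
        edge_weight=np.asarray(weights, dtype=float),
        cutoff=cutoff,
    )


def zeroed_model(cfg, dtype=np.float64):
    m = SurrogateModel(cfg, rng=np.random.default_rng(0), dtype=dtype)
    for p in m.parameters():
        p[...] = 0
    return m


class TestCountWeights:
    @pytest.mark.parametrize(
        "K,L,expected",
        [(64, 5, 17350), (1, 1, 13), (2, 2, 31)],
    )
    def test_closed_form(self, K, L, expected):
        assert count_weights(SurrogateConfig(K=K, L=L)) == expected

    def test_census_matches_formula_for_random_shapes(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            K = int(rng.integers(1, 40))
            L = int(rng.integers(1, 7))
            cfg = SurrogateConfig(K=K, L=L)
            model = SurrogateModel(cfg, rng=rng)
            assert model.num_weights(exclude_bias=True) == count_weights(cfg)


class TestEmbedVertices:
    def test_zero_input_zero_bias(self):
        cfg = SurrogateConfig(K=4, L=2)
        m = zeroed_model(cfg)
        g = graph_from(np.zeros((3, 10)), np.empty((0, 2)), [])
        np.testing.assert_array_equal(embed_vertices(g, m), np.zeros((3, 4)))

    def test_identical_features_identical_embeddings(self):
        cfg = SurrogateConfig(K=6, L=2)
        m = SurrogateModel(cfg, rng=np.random.default_rng(1), dtype=np.float64)
        feats = np.tile([1, 0, 0, 0, 1, 0, 0, 0, 1, 0], (4, 1))
        g = graph_from(feats, np.empty((0, 2)), [])
        h = embed_vertices(g, m)
        assert np.allclose(h, h[0])

    def test_identity_like_weights_pass_one_hot(self):
        cfg = SurrogateConfig(K=10, L=1)
        m = zeroed_model(cfg)
        m.W_embed[...] = np.eye(10)
        g = graph_from(np.eye(10)[:1], np.empty((0, 2)), [])
        np.testing.assert_array_equal(embed_vertices(g, m)[0], np.eye(10)[0])


class TestGinLayer:
    def test_isolated_vertex_empty_neighbor_sum(self):
        cfg = SurrogateConfig(K=2, L=2)
        m = zeroed_model(cfg)
        m.W_conv[0][...] = np.eye(2)
        g = graph_from(np.zeros((1, 10)), np.empty((0, 2)), [])
        h = np.array([[1.5, -2.0]])
        np.testing.assert_allclose(gin_layer(h, g, 0, m), [[1.5, 0.0]])

    def test_hand_computed_neighbor_aggregation(self):
        """v=(1,0) with eps=0.5, neighbor (2,2) at weight 0.25, identity MLP:
        pre_v = 1.5*(1,0) + 0.25*(2,2) = (2.0, 0.5)."""
        cfg = SurrogateConfig(K=2, L=2)
        m = zeroed_model(cfg)
        m.W_conv[0][...] = np.eye(2)
        m.eps[0] = 0.5
        g = graph_from(np.zeros((2, 10)), [[0, 1]], [0.25])
        h = np.array([[1.0, 0.0], [2.0, 2.0]])
        out = gin_layer(h, g, 0, m)
        np.testing.assert_allclose(out[0], [2.0, 0.5])

    def test_linearity_in_edge_weight(self):
        cfg = SurrogateConfig(K=2, L=2)
        m = zeroed_model(cfg)
        m.W_conv[0][...] = np.eye(2)
        h = np.array([[0.0, 0.0], [3.0, 1.0]])
        g1 = graph_from(np.zeros((2, 10)), [[0, 1]], [0.5])
        g2 = graph_from(np.zeros((2, 10)), [[0, 1]], [1.0])
        np.testing.assert_allclose(2 * gin_layer(h, g1, 0, m)[0], gin_layer(h, g2, 0, m)[0])


class TestReadout:
    def test_zero_weight_paths_give_zero(self):
        cfg = SurrogateConfig(K=3, L=2)
        m = zeroed_model(cfg)
        states = [np.ones((4, 3)), np.ones((4, 3))]
        assert readout(states, me.Mapping(n=4, retained=(0,)), m) == 0.0

    def test_degenerate_hand_example(self):
        """K=1, L=1: retained state 3 with w_s=2, non-retained 5 with w_n=-1,
        w_out=1 gives 2*3 - 1*5 = 1."""
        cfg = SurrogateConfig(K=1, L=1)
        m = zeroed_model(cfg)
        m.w_site[...] = 2.0
        m.w_nonsite[...] = -1.0
        m.w_out[...] = 1.0
        states = [np.array([[3.0], [5.0]])]
        assert readout(states, me.Mapping(n=2, retained=(0,)), m) == pytest.approx(1.0)


class TestPredict:
    def test_all_zero_weights_zero_prediction(self, tiny_graph):
        cfg = SurrogateConfig(K=4, L=3)
        m = zeroed_model(cfg)
        assert predict(tiny_graph, me.Mapping(n=10, retained=(0, 1)), m) == 0.0

    def test_matches_manual_composition(self, tiny_graph):
        cfg = SurrogateConfig(K=8, L=3)
        m = SurrogateModel(cfg, rng=np.random.default_rng(5), dtype=np.float64)
        mp = me.Mapping(n=10, retained=(1, 4, 8))
        g = me.encode_mapping(tiny_graph, mp)
        states = [embed_vertices(g, m)]
        for layer in range(cfg.L - 1):
            states.append(gin_layer(states[-1], g, layer, m))
        assert predict(tiny_graph, mp, m) == pytest.approx(
            readout(states, mp, m), rel=1e-12
        )

    def test_permutation_invariance(self, tiny_graph, rng):
        """Relabeling vertices consistently leaves the prediction unchanged."""
        cfg = SurrogateConfig(K=8, L=3)
        m = SurrogateModel(cfg, rng=np.random.default_rng(6), dtype=np.float64)
        mp = me.Mapping(n=10, retained=(0, 3, 7))
        base = predict(tiny_graph, mp, m)
        perm = rng.permutation(10)
        inv = np.argsort(perm)
        g2 = ProteinGraph(
            features=tiny_graph.features[perm],
            edges=np.sort(inv[tiny_graph.edges], axis=1),
            edge_weight=tiny_graph.edge_weight,
            cutoff=tiny_graph.cutoff,
        )
        mp2 = me.Mapping(n=10, retained=tuple(int(inv[i]) for i in mp.retained))
        assert predict(g2, mp2, m) == pytest.approx(base, rel=1e-10)

    def test_site_bit_changes_prediction(self, tiny_graph):
        """Generic weights are sensitive to the mapping encoding."""
        cfg = SurrogateConfig(K=8, L=3)
        m = SurrogateModel(cfg, rng=np.random.default_rng(7), dtype=np.float64)
        a = predict(tiny_graph, me.Mapping(n=10, retained=(0, 1, 2)), m)
        b = predict(tiny_graph, me.Mapping(n=10, retained=(0, 1, 3)), m)
        assert a != b

    def test_batch_matches_single(self, tiny_graph, rng):
        cfg = SurrogateConfig(K=8, L=3)
        m = SurrogateModel(cfg, rng=np.random.default_rng(8), dtype=np.float64)
        mappings = [me.random_mapping(10, 3, rng) for _ in range(5)]
        batched = predict_batch(tiny_graph, mappings, m)
        singles = [predict(tiny_graph, mp, m) for mp in mappings]
        np.testing.assert_allclose(batched, singles, rtol=1e-10)


class TestEvaluate:
    def test_perfect_and_mean_predictors(self):
        y = np.array([1.0, 2.0, 3.0])
        assert evaluate(y, y) == (pytest.approx(1.0), pytest.approx(0.0))
        r2, _ = evaluate(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_example(self):
        r2, mae = evaluate(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.0, 3.0]))
        assert mae == pytest.approx(2.0 / 3.0)
        assert r2 == pytest.approx(0.0)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.ones(4), np.arange(4.0))


class TestTraining:
    def test_constant_target_learned(self, tiny_graph, rng):
        mappings = [me.random_mapping(10, 3, rng) for _ in range(40)]
        samples = [me.MappingSample(mapping=m, smap=7.5) for m in mappings]
        cfg = SurrogateConfig(K=8, L=2, seed=0, max_epochs=30, patience=30)
        res = train(tiny_graph, samples, cfg)
        assert res.log[-1]["train_mae"] <= 1e-2 * 7.5

    def test_seeded_determinism(self, tiny_graph, rng):
        mappings = [me.random_mapping(10, 3, rng) for _ in range(30)]
        samples = [
            me.MappingSample(mapping=m, smap=float(i)) for i, m in enumerate(mappings)
        ]
        cfg = SurrogateConfig(K=4, L=2, seed=42, max_epochs=10, patience=10)
        log_a = train(tiny_graph, samples, cfg).log
        log_b = train(tiny_graph, samples, cfg).log
        assert log_a == log_b  # bitwise-identical epoch logs

    def test_best_validation_never_worsens(self, tiny_graph, rng):
        mappings = [me.random_mapping(10, 4, rng) for _ in range(60)]
        oc = me.ToyOracle(tiny_graph)
        samples = [me.MappingSample(mapping=m, smap=oc(m)) for m in mappings]
        cfg = SurrogateConfig(K=8, L=3, seed=1, max_epochs=40, patience=40)
        res = train(tiny_graph, samples, cfg)
        best = [row["best_val_mae"] for row in res.log]
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_too_few_samples_rejected(self, tiny_graph):
        with pytest.raises(ValueError):
            train(tiny_graph, [], SurrogateConfig(K=2, L=2))


def test_model_save_load_round_trip(tiny_graph, tmp_path, rng):
    cfg = SurrogateConfig(K=8, L=3, seed=2)
    model = SurrogateModel(cfg, rng=np.random.default_rng(2))
    mp = me.random_mapping(10, 3, rng)
    path = tmp_path / "model.npz"
    me.save_model(model, path)
    back = me.load_model(path)
    assert predict(tiny_graph, mp, back) == pytest.approx(
        predict(tiny_graph, mp, model), rel=1e-6
    )


def test_dataset_save_load_round_trip(tmp_path, rng):
    samples = [
        me.MappingSample(mapping=me.random_mapping(20, 5, rng), smap=float(i), origin=o)
        for i, o in enumerate(["random", "optimized", "random"])
    ]
    path = tmp_path / "data.jsonl"
    me.save_dataset(samples, path)
    back = me.load_dataset(path, n=20)
    assert [s.mapping for s in back] == [s.mapping for s in samples]
    assert [s.origin for s in back] == ["random", "optimized", "random"]
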