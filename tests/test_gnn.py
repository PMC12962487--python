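"""Model: attention semantics, pooling, invariances, parameter counts."""

import numpy as np
import pytest

from graphscreen import nn
from graphscreen.datasplit import randomize_smiles
from graphscreen.featurize import build_graph, fit_scaler
from graphscreen.gnn import (
    GraphAttentionLayer,
    GraphBatch,
    GraphScreenModel,
    ModelConfig,
    attention_coefficients,
    count_parameters,
    dual_pool,
    load_checkpoint,
    save_checkpoint,
)


class TestAttentionCoefficients:
    def test_hand_computed_two_element_softmax(self):
        # 1-dim toy: h_i=1, neighbors {1,2}, W_s=W_t=1, a=1, slope 0.2
        alpha = attention_coefficients(
            np.array([1.0]), np.array([[1.0], [2.0]]),
            np.array([[1.0]]), np.array([[1.0]]), np.array([1.0]), mode="gatv2",
        )
        expected = np.exp([2.0, 3.0]) / np.exp([2.0, 3.0]).sum()
        assert np.allclose(alpha, expected)
        assert alpha[0] == pytest.approx(0.2689, abs=1e-4)
        assert alpha[1] == pytest.approx(0.7311, abs=1e-4)

    @pytest.mark.parametrize("mode", ["gat", "gatv2"])
    def test_single_neighbor_gives_one(self, mode, rng):
        d = 4
        a_dim = d if mode == "gatv2" else 2 * d
        alpha = attention_coefficients(
            rng.normal(size=d), rng.normal(size=(1, d)),
            rng.normal(size=(d, d)), rng.normal(size=(d, d)),
            rng.normal(size=a_dim), mode=mode,
        )
        assert alpha.shape == (1,) and alpha[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["gat", "gatv2"])
    def test_identical_neighbors_share_weight_equally(self, mode, rng):
        d, k = 3, 5
        h_j = rng.normal(size=d)
        a_dim = d if mode == "gatv2" else 2 * d
        alpha = attention_coefficients(
            rng.normal(size=d), np.tile(h_j, (k, 1)),
            rng.normal(size=(d, d)), rng.normal(size=(d, d)),
            rng.normal(size=a_dim), mode=mode,
        )
        assert np.allclose(alpha, 1.0 / k)

    def test_empty_neighborhood_raises(self):
        with pytest.raises(ValueError):
            attention_coefficients(
                np.array([1.0]), np.zeros((0, 1)),
                np.eye(1), np.eye(1), np.array([1.0]),
            )


def _random_batched_graph(rng, n_graphs=50, in_dim=8):
    """Disjoint union of small random connected graphs with self-loops."""
    xs, srcs, dsts, gids = [], [], [], []
    offset = 0
    for gid in range(n_graphs):
        n = int(rng.integers(1, 7))
        xs.append(rng.normal(size=(n, in_dim)))
        for i in range(1, n):  # random tree keeps it connected
            j = int(rng.integers(0, i))
            srcs += [offset + i, offset + j]
            dsts += [offset + j, offset + i]
        loop = np.arange(n) + offset
        srcs += loop.tolist()
        dsts += loop.tolist()
        gids += [gid] * n
        offset += n
    x = np.concatenate(xs)
    src, dst = np.array(srcs), np.array(dsts)
    efeat = rng.normal(size=(len(src), 12))
    return x, src, dst, efeat, np.array(gids), offset


class TestAttentionLayer:
    @pytest.mark.parametrize("mode", ["gat", "gatv2"])
    def test_attention_rows_sum_to_one_random_graphs(self, mode, rng):
        cfg = ModelConfig(hidden_dim=6, n_heads=3, n_layers=1, attention_mode=mode,
                          atom_dim=8)
        x, src, dst, efeat, _, n_nodes = _random_batched_graph(rng, n_graphs=1000)
        layer = GraphAttentionLayer(8, cfg, rng)
        _, attentions = layer.forward(
            nn.Tensor(x), src, dst, efeat, n_nodes, train=False,
            rng=rng, return_attention=True,
        )
        for alpha in attentions:
            assert np.all(alpha > 0)
            sums = np.zeros(n_nodes)
            np.add.at(sums, dst, alpha)
            assert np.allclose(sums, 1.0, atol=1e-6)

    def test_eval_mode_deterministic(self, rng, tiny_model_config):
        x, src, dst, efeat, _, n_nodes = _random_batched_graph(rng, n_graphs=5)
        layer = GraphAttentionLayer(8, ModelConfig(hidden_dim=4, n_heads=2, atom_dim=8), rng)
        o1 = layer.forward(nn.Tensor(x), src, dst, efeat, n_nodes, False, rng)
        o2 = layer.forward(nn.Tensor(x), src, dst, efeat, n_nodes, False, rng)
        assert np.array_equal(o1.data, o2.data)

    def test_permutation_equivariance(self, rng):
        cfg = ModelConfig(hidden_dim=5, n_heads=2, atom_dim=8, use_batch_norm=False)
        layer = GraphAttentionLayer(8, cfg, rng)
        x, src, dst, efeat, _, n = _random_batched_graph(rng, n_graphs=4)
        out = layer.forward(nn.Tensor(x), src, dst, efeat, n, False, rng).data
        perm = rng.permutation(n)
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)
        out_p = layer.forward(
            nn.Tensor(x[perm]), inv[src], inv[dst], efeat, n, False, rng
        ).data
        assert np.allclose(out_p[inv], out, atol=1e-10)

    def test_missing_self_loop_raises(self, rng):
        layer = GraphAttentionLayer(8, ModelConfig(hidden_dim=4, n_heads=1, atom_dim=8), rng)
        x = rng.normal(size=(3, 8))
        # node 2 has no incoming edge at all
        src, dst = np.array([0, 1]), np.array([1, 0])
        with pytest.raises(ValueError, match="self-loops"):
            layer.forward(nn.Tensor(x), src, dst, np.zeros((2, 12)), 3, False, rng)

    def test_static_attention_ranking_is_center_independent(self, rng):
        """GAT's score is monotone in (center-term + neighbor-term), so the
        ranking of a fixed neighbor set cannot depend on the center node;
        GATv2's dynamic scoring can (and generically does) re-rank."""
        d = 6
        w_s, w_t = rng.normal(size=(d, d)), rng.normal(size=(d, d))
        neighbors = rng.normal(size=(5, d))
        centers = rng.normal(size=(8, d))
        gat_rankings, gatv2_rankings = set(), set()
        a_gat, a_v2 = rng.normal(size=2 * d), rng.normal(size=d)
        for c in centers:
            gat = attention_coefficients(c, neighbors, w_s, w_t, a_gat, mode="gat")
            v2 = attention_coefficients(c, neighbors, w_s, w_t, a_v2, mode="gatv2")
            gat_rankings.add(tuple(np.argsort(gat)))
            gatv2_rankings.add(tuple(np.argsort(v2)))
        assert len(gat_rankings) == 1
        assert len(gatv2_rankings) > 1


class TestPooling:
    def test_single_atom_mean_equals_max(self):
        h = nn.Tensor(np.array([[1.0, -2.0, 3.0]]))
        g = dual_pool(h, np.array([0]), 1)
        assert np.allclose(g.data, [[1.0, -2.0, 3.0, 1.0, -2.0, 3.0]])

    def test_direct_mean_max(self):
        h = nn.Tensor(np.array([[0.0, 2.0], [2.0, 0.0]]))
        g = dual_pool(h, np.array([0, 0]), 1)
        assert np.allclose(g.data, [[1.0, 1.0, 2.0, 2.0]])

    def test_permutation_invariance(self, rng):
        h = rng.normal(size=(7, 4))
        gids = np.array([0, 0, 0, 1, 1, 2, 2])
        ref = dual_pool(nn.Tensor(h), gids, 3).data
        perm = rng.permutation(7)
        assert np.allclose(dual_pool(nn.Tensor(h[perm]), gids[perm], 3).data, ref)

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            dual_pool(nn.Tensor(np.zeros((2, 3))), np.array([0, 0]), 2)


class TestModelForward:
    def test_probability_in_open_interval(self, tiny_model_config, rng):
        model = GraphScreenModel(tiny_model_config, seed=0)
        graphs = [build_graph(s) for s in ["C", "CCO", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1"]]
        p = model.forward(GraphBatch.from_graphs(graphs)).data
        assert p.shape == (4, 1)
        assert np.all((p > 0) & (p < 1))

    def test_prediction_invariant_to_smiles_spelling(self, tiny_model_config):
        model = GraphScreenModel(tiny_model_config, seed=1)
        smiles = "CC(=O)Nc1ccc(O)cc1"
        ref = model.predict_proba([build_graph(smiles)])
        for variant in randomize_smiles(smiles, max_variants=3, seed=2):
            p = model.predict_proba([build_graph(variant)])
            assert p == pytest.approx(ref, abs=1e-10)

    def test_descriptor_branch_output_length_and_zero_weights(self, tiny_model_config, rng):
        model = GraphScreenModel(tiny_model_config, seed=0)
        d = nn.Tensor(rng.normal(size=(3, 50)))
        out = model.descriptor_branch(d, train=False, rng=rng)
        assert out.data.shape == (3, 32)
        for p in model.desc1.parameters() + model.desc2.parameters():
            p.data[...] = 0.0
        assert np.allclose(model.descriptor_branch(d, False, rng).data, 0.0)

    def test_no_descriptor_ablation_changes_head_width(self):
        cfg = ModelConfig(hidden_dim=8, n_heads=2, n_layers=1, use_descriptors=False)
        assert cfg.fused_dim == cfg.graph_embedding_dim
        model = GraphScreenModel(cfg, seed=0)
        p = model.predict_proba([build_graph("CCO")])
        assert 0 < p[0] < 1

    def test_mean_only_pooling_ablation(self):
        cfg = ModelConfig(hidden_dim=8, n_heads=2, n_layers=1, pooling="mean_only")
        assert cfg.graph_embedding_dim == 8
        model = GraphScreenModel(cfg, seed=0)
        assert 0 < model.predict_proba([build_graph("CCO")])[0] < 1

    def test_descriptor_scaler_applied_in_batch(self, tiny_model_config, rng):
        model = GraphScreenModel(tiny_model_config, seed=0)
        graphs = [build_graph("CCOC"), build_graph("c1ccccc1")]
        scaler = fit_scaler(rng.normal(size=(20, 50)))
        p_scaled = model.predict_proba(graphs, scaler)
        p_raw = model.predict_proba(graphs)
        assert not np.allclose(p_scaled, p_raw)


class TestParameterCount:
    def test_descriptor_branch_dense_arithmetic(self):
        model = GraphScreenModel(ModelConfig(hidden_dim=4, n_heads=1, n_layers=1), seed=0)
        n = sum(p.data.size for p in model.desc1.parameters() + model.desc2.parameters())
        assert n == (50 * 64 + 64) + (64 * 32 + 32) == 5344

    def test_final_head_dense_arithmetic(self):
        model = GraphScreenModel(ModelConfig(), seed=0)
        head = sum(p.data.size for p in model.head1.parameters() + model.head2.parameters())
        bn = sum(p.data.size for p in model.head_norm.parameters())
        assert head == (544 * 512 + 512) + (512 * 1 + 1) == 279040 + 513
        assert bn == 1024

    def test_default_model_near_2_8_million(self):
        n = count_parameters(ModelConfig())
        assert abs(n - 2.8e6) / 2.8e6 < 0.10


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tiny_model_config, tmp_path, rng):
        model = GraphScreenModel(tiny_model_config, seed=3)
        scaler = fit_scaler(rng.normal(size=(10, 50)))
        graphs = [build_graph("CC(=O)Nc1ccc(O)cc1"), build_graph("CCO")]
        ref = model.predict_proba(graphs, scaler)
        path = tmp_path / "model.ckpt"
        save_checkpoint(path, model, scaler)
        loaded, loaded_scaler = load_checkpoint(path)
        assert np.array_equal(loaded.predict_proba(graphs, loaded_scaler), ref)

    def test_refuses_mismatched_config(self, tiny_model_config, tmp_path):
        path = tmp_path / "model.ckpt"
        save_checkpoint(path, GraphScreenModel(tiny_model_config, seed=0))
        with pytest.raises(ValueError, match="config"):
            load_checkpoint(path, expected_config=ModelConfig(hidden_dim=99))
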