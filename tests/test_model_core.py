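"""Network components against independent dense-algebra/double-loop oracles."""

import numpy as np
import pytest

from ppisite.autograd import Tensor
from ppisite.model_core import (
    ModelConfig,
    SiteModel,
    agat_attention_layer,
    att_fusion,
    beta_schedule,
    gcnii_layer,
    graph_pool,
    load_checkpoint,
    normalized_propagation,
    save_checkpoint,
    subgraph_conv_layer,
)
from ppisite.sol_objective import total_loss
from conftest import random_graph


def make_adjacency(rng, n):
    adj = rng.random((n, n)) < 0.4
    adj = adj | adj.T
    np.fill_diagonal(adj, True)
    return adj


class TestPropagation:
    def test_single_node(self):
        np.testing.assert_allclose(normalized_propagation(np.ones((1, 1))), [[1.0]])

    def test_three_clique(self):
        P = normalized_propagation(np.ones((3, 3)))
        np.testing.assert_allclose(P, np.full((3, 3), 1 / 3))
        np.testing.assert_allclose(P.sum(axis=1), 1.0)

    def test_matches_dense_linear_algebra(self, rng):
        adj = make_adjacency(rng, 8)
        D = np.diag(adj.sum(axis=1).astype(float))
        expected = np.linalg.inv(np.sqrt(D)) @ adj @ np.linalg.inv(np.sqrt(D))
        np.testing.assert_allclose(normalized_propagation(adj), expected, atol=1e-12)


class TestBetaSchedule:
    def test_zero_lambda_gives_zero(self):
        assert beta_schedule(3, 0.0) == 0.0

    def test_lambda_equals_layer_gives_ln2(self):
        assert beta_schedule(4, 4.0) == pytest.approx(np.log(2))

    def test_monotone_decreasing(self):
        values = [beta_schedule(l, 0.5) for l in range(1, 5)]
        assert all(a > b for a, b in zip(values, values[1:]))
        np.testing.assert_allclose(
            values, [np.log(0.5 / l + 1) for l in range(1, 5)]
        )

    def test_printed_form_is_increasing(self):
        values = [beta_schedule(l, 0.5, printed_form=True) for l in range(1, 5)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_layer_zero_rejected(self):
        with pytest.raises(ValueError):
            beta_schedule(0, 1.0)


class TestGraphPool:
    def test_ratio_one_keeps_everything(self, rng):
        adj = make_adjacency(rng, 6)
        H = Tensor(rng.standard_normal((6, 4)))
        w = Tensor(rng.standard_normal(4), requires_grad=True)
        selected, H_pool, induced = graph_pool(H, adj, 1.0, w)
        np.testing.assert_array_equal(selected, np.arange(6))
        np.testing.assert_array_equal(induced, adj)

    def test_top_k_selection_with_scores(self):
        # engineered scores [3, 1, 2, 1] via w = e0 and unit-norm trick
        H = Tensor(np.array([[3.0], [1.0], [2.0], [1.0]]))
        w = Tensor(np.array([1.0]))
        selected, _, _ = graph_pool(H, np.eye(4, dtype=bool), 0.5, w)
        np.testing.assert_array_equal(selected, [0, 2])

    def test_ties_break_to_lower_index(self):
        H = Tensor(np.array([[1.0], [2.0], [2.0], [2.0]]))
        selected, _, _ = graph_pool(H, np.eye(4, dtype=bool), 0.5, Tensor([1.0]))
        np.testing.assert_array_equal(selected, [1, 2])

    def test_floor_keeps_at_least_one_node(self, rng):
        H = Tensor(rng.standard_normal((3, 2)))
        selected, _, _ = graph_pool(H, np.eye(3, dtype=bool), 0.01, Tensor(rng.standard_normal(2)))
        assert len(selected) == 1

    def test_induced_adjacency_matches_subsetting(self, rng):
        adj = make_adjacency(rng, 10)
        H = Tensor(rng.standard_normal((10, 5)))
        w = Tensor(rng.standard_normal(5))
        selected, H_pool, induced = graph_pool(H, adj, 0.4, w)
        np.testing.assert_array_equal(induced, adj[np.ix_(selected, selected)])
        # gating: rows are sigmoid(score)-scaled rows of H
        scores = (H.data @ w.data) / np.linalg.norm(w.data)
        gate = 1 / (1 + np.exp(-scores[selected]))
        np.testing.assert_allclose(H_pool.data, H.data[selected] * gate[:, None])


class TestSubgraphConv:
    def _random_inputs(self, rng, n=5, d=4):
        adj = make_adjacency(rng, n)
        P = normalized_propagation(adj)
        H = Tensor(rng.standard_normal((n, d)))
        H0 = Tensor(rng.standard_normal((n, d)))
        W = Tensor(rng.standard_normal((d, d)))
        return P, H, H0, W

    def test_alpha0_beta0_reduces_to_plain_propagation(self, rng):
        P, H, H0, W = self._random_inputs(rng)
        out = subgraph_conv_layer(H, H0, P, W, alpha=0.0, beta=0.0)
        np.testing.assert_allclose(out.data, np.maximum(P @ H.data, 0), atol=1e-12)

    def test_alpha1_is_independent_of_current_state(self, rng):
        P, H, H0, W = self._random_inputs(rng)
        beta = 0.3
        out = subgraph_conv_layer(H, H0, P, W, alpha=1.0, beta=beta)
        expected = np.maximum(
            H0.data @ ((1 - beta) * np.eye(4) + beta * W.data), 0
        )
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_matches_dense_evaluation(self, rng):
        for _ in range(100):
            P, H, H0, W = self._random_inputs(rng)
            alpha, beta = rng.random(), rng.random()
            out = subgraph_conv_layer(H, H0, P, W, alpha=alpha, beta=beta)
            support = (1 - alpha) * (P @ H.data) + alpha * H0.data
            expected = np.maximum(
                support @ ((1 - beta) * np.eye(4) + beta * W.data), 0
            )
            np.testing.assert_allclose(out.data, expected, rtol=1e-10, atol=1e-12)

    def test_width_mismatch_raises(self, rng):
        P, H, _, W = self._random_inputs(rng)
        with pytest.raises(ValueError):
            subgraph_conv_layer(H, Tensor(np.zeros((5, 3))), P, W, 0.5, 0.5)


def attention_params(rng, d, d_edge, n_heads):
    params = {}
    for k in range(n_heads):
        params[f"Wh{k}"] = Tensor(rng.standard_normal((d, d)))
        params[f"We{k}"] = Tensor(rng.standard_normal((d_edge, d)))
        params[f"a_dst{k}"] = Tensor(rng.standard_normal(d))
        params[f"a_src{k}"] = Tensor(rng.standard_normal(d))
        params[f"a_edge{k}"] = Tensor(rng.standard_normal(d))
    return params


def attention_oracle(H, adj, efeat, params, k, slope=0.2):
    """Explicit double-loop evaluation of one attention head."""
    n, d = H.shape
    Wh, We = params[f"Wh{k}"].data, params[f"We{k}"].data
    a = np.concatenate([params[f"a_dst{k}"].data, params[f"a_src{k}"].data, params[f"a_edge{k}"].data])
    out = np.zeros((n, d))
    coeffs = np.zeros((n, n))
    for i in range(n):
        neighbors = [j for j in range(n) if adj[i, j]]
        logits = []
        for j in neighbors:
            z = np.concatenate([Wh.T @ H[i], Wh.T @ H[j], We.T @ efeat[(i, j)]])
            e = float(a @ z)
            logits.append(e if e > 0 else slope * e)
        logits = np.array(logits)
        weights = np.exp(logits - logits.max())
        weights /= weights.sum()
        for j, wgt in zip(neighbors, weights):
            coeffs[i, j] = wgt
            out[i] += wgt * (Wh.T @ H[j])
    return out, coeffs


class TestAGATAttention:
    def _graph(self, rng, n=6, d=4, d_edge=2):
        adj = make_adjacency(rng, n)
        src, dst = np.nonzero(adj)
        edge_index = np.stack([src, dst])
        efeat_map = {}
        feats = np.zeros((len(src), d_edge))
        for e, (i, j) in enumerate(zip(src, dst)):
            key = (min(i, j), max(i, j))
            if key not in efeat_map:
                efeat_map[key] = rng.random(d_edge)
            feats[e] = efeat_map[key]
        lookup = {(i, j): feats[e] for e, (i, j) in enumerate(zip(src, dst))}
        return adj, edge_index, feats, lookup

    def test_isolated_node_attends_to_itself(self, rng):
        params = attention_params(rng, 3, 2, 1)
        H = Tensor(rng.standard_normal((1, 3)))
        out = agat_attention_layer(
            H, np.array([[0], [0]]), np.zeros((1, 2)), params, n_heads=1
        )
        np.testing.assert_allclose(out.data, H.data @ params["Wh0"].data, atol=1e-12)

    def test_identical_neighbors_get_uniform_coefficients(self, rng):
        n = 4
        adj = np.ones((n, n), dtype=bool)
        src, dst = np.nonzero(adj)
        H = Tensor(np.tile(rng.standard_normal(3), (n, 1)))
        params = attention_params(rng, 3, 2, 1)
        _, coeff = agat_attention_layer(
            H, np.stack([src, dst]), np.ones((n * n, 2)), params,
            n_heads=1, return_coefficients=True,
        )
        np.testing.assert_allclose(coeff.data, 1.0 / n, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            adj, edge_index, feats, lookup = self._graph(rng)
            H = Tensor(rng.standard_normal((6, 4)))
            params = attention_params(rng, 4, 2, 2)
            out = agat_attention_layer(H, edge_index, feats, params, n_heads=2)
            expected = np.mean(
                [attention_oracle(H.data, adj, lookup, params, k)[0] for k in range(2)],
                axis=0,
            )
            np.testing.assert_allclose(out.data, expected, rtol=1e-8, atol=1e-10)

    def test_coefficient_rows_sum_to_one(self, rng):
        adj, edge_index, feats, _ = self._graph(rng, n=9)
        H = Tensor(rng.standard_normal((9, 4)))
        params = attention_params(rng, 4, 2, 1)
        _, coeff = agat_attention_layer(
            H, edge_index, feats, params, n_heads=1, return_coefficients=True
        )
        sums = np.zeros(9)
        np.add.at(sums, edge_index[1], coeff.data[:, 0])
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_missing_edge_feature_rejected(self, rng):
        params = attention_params(rng, 3, 2, 1)
        with pytest.raises(ValueError):
            agat_attention_layer(
                Tensor(np.zeros((2, 3))), np.array([[0, 1], [1, 0]]),
                np.zeros((1, 2)), params, n_heads=1,
            )


class TestGCNIILayer:
    def test_limit_identities(self, rng):
        H_in = Tensor(rng.standard_normal((5, 4)))
        H0 = Tensor(rng.standard_normal((5, 4)))
        W = Tensor(rng.standard_normal((8, 4)))
        out = gcnii_layer(H_in, H0, W, alpha=0.0, beta=0.0)
        np.testing.assert_allclose(out.data, np.maximum(H_in.data, 0), atol=1e-12)
        out = gcnii_layer(H_in, H0, W, alpha=1.0, beta=0.0)
        np.testing.assert_allclose(out.data, np.maximum(H0.data, 0), atol=1e-12)

    def test_matches_dense_evaluation(self, rng):
        for _ in range(100):
            H_in = Tensor(rng.standard_normal((5, 4)))
            H0 = Tensor(rng.standard_normal((5, 4)))
            W = Tensor(rng.standard_normal((8, 4)))
            alpha, beta = rng.random(), rng.random()
            out = gcnii_layer(H_in, H0, W, alpha=alpha, beta=beta)
            expected = np.maximum(
                (1 - beta) * ((1 - alpha) * H_in.data + alpha * H0.data)
                + beta * (np.hstack([H_in.data, H0.data]) @ W.data),
                0,
            )
            np.testing.assert_allclose(out.data, expected, rtol=1e-10, atol=1e-12)

    def test_bad_weight_shape_rejected(self, rng):
        with pytest.raises(ValueError):
            gcnii_layer(
                Tensor(np.zeros((5, 4))), Tensor(np.zeros((5, 4))),
                Tensor(np.zeros((4, 4))), 0.5, 0.5,
            )


class TestAttFusion:
    def test_single_row_passes_value_through(self, rng):
        H_sub = Tensor(rng.standard_normal((1, 3)))
        H_agat = Tensor(rng.standard_normal((1, 5)))
        np.testing.assert_allclose(att_fusion(H_sub, H_agat).data, H_agat.data)

    def test_zero_query_gives_uniform_attention(self, rng):
        H_agat = Tensor(rng.standard_normal((6, 4)))
        out = att_fusion(Tensor(np.zeros((6, 3))), H_agat)
        np.testing.assert_allclose(
            out.data, np.tile(H_agat.data.mean(axis=0), (6, 1)), atol=1e-12
        )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 50))
            H_sub = Tensor(rng.standard_normal((n, 8)))
            H_agat = Tensor(rng.standard_normal((n, 16)))
            out = att_fusion(H_sub, H_agat)
            expected = np.zeros((n, 16))
            for i in range(n):
                logits = np.array(
                    [H_sub.data[i] @ H_sub.data[j] / np.sqrt(8) for j in range(n)]
                )
                weights = np.exp(logits - logits.max())
                weights /= weights.sum()
                expected[i] = weights @ H_agat.data
            np.testing.assert_allclose(out.data, expected, rtol=1e-6, atol=1e-8)

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            att_fusion(Tensor(np.zeros((3, 2))), Tensor(np.zeros((4, 2))))


def small_config(**kw):
    defaults = dict(d_hidden=16, n_layers_sub=2, n_layers_agat=2, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestForward:
    def test_probability_rows_sum_to_one(self, small_graph):
        model = SiteModel(small_config(), d_node=8)
        result = model.predict(small_graph)
        np.testing.assert_allclose(result.probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(result.calls, (result.probs[:, 1] >= 0.5).astype(int))

    def test_eval_forward_is_deterministic(self, small_graph):
        model = SiteModel(small_config(seed=3), d_node=8)
        a = model.predict(small_graph).probs
        b = model.predict(small_graph).probs
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("n", [1, 2, 10, 200])
    def test_forward_is_finite_across_sizes(self, rng, n):
        graph = random_graph(rng, n=n, d_node=6, cutoff=20.0)
        model = SiteModel(small_config(), d_node=6)
        probs = model.predict(graph).probs
        assert probs.shape == (n, 2) and np.isfinite(probs).all()

    def test_permutation_equivariance_up_to_pooling(self, rng):
        # spread coords widely so pooling scores are tie-free
        graph = random_graph(rng, n=14, d_node=6, cutoff=18.0)
        model = SiteModel(small_config(seed=5), d_node=6)
        base = model.predict(graph).probs
        perm = rng.permutation(14)
        from ppisite.residue_graph import build_graph

        permuted = build_graph(
            graph.coords[perm], graph.node_features[perm], cutoff=graph.cutoff
        )
        # sequence-separation edge features are order-dependent; neutralize
        # them so only the graph structure matters for this check
        permuted.edge_features[:, 1] = 0.0
        graph2 = build_graph(graph.coords, graph.node_features, cutoff=graph.cutoff)
        graph2.edge_features[:, 1] = 0.0
        probs_perm = model.predict(permuted).probs
        probs_base = model.predict(graph2).probs
        np.testing.assert_allclose(probs_perm[np.argsort(perm)], probs_base, atol=1e-5)

    def test_every_parameter_receives_gradient(self, small_graph):
        model = SiteModel(small_config(dropout=0.0), d_node=8)
        probs = model.forward_tensor(small_graph, train=True)
        loss, _ = total_loss(probs, small_graph.labels)
        loss.backward()
        dead = [
            name
            for name, p in model.params.items()
            if p.grad is None or not np.abs(p.grad).any()
        ]
        assert not dead, f"parameters with no gradient: {dead}"


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, small_graph):
        model = SiteModel(small_config(seed=9), d_node=8)
        before = model.predict(small_graph).probs
        save_checkpoint(model, tmp_path / "m.ckpt")
        loaded = load_checkpoint(tmp_path / "m.ckpt")
        np.testing.assert_array_equal(loaded.predict(small_graph).probs, before)

    def test_mismatched_config_refused(self, tmp_path):
        model = SiteModel(small_config(), d_node=8)
        save_checkpoint(model, tmp_path / "m.ckpt")
        with pytest.raises(ValueError, match="config"):
            load_checkpoint(tmp_path / "m.ckpt", expected_config=small_config(d_hidden=32))
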