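"""SAT encoder: subgraph extraction, structural limits, invariances."""

import numpy as np
import pytest

from atlasfuse.atlas import AtlasSpec
from atlasfuse.fc_graphs import BrainGraph
from atlasfuse.sat import (
    SATConfig,
    encode_graph,
    extract_khop_subgraph,
    khop_masks,
    sat_params,
)
from conftest import random_graph


def tiny_cfg(**kw):
    base = dict(k_hops=1, n_layers=1, hidden_dim=4, n_heads=2, dropout_rate=0.0, gnn_layers=2)
    base.update(kw)
    return SATConfig(**base)


class TestKhopSubgraph:
    def test_k0_is_root_only(self, path_graph):
        sg = extract_khop_subgraph(path_graph, 2, 0)
        assert sg.member_nodes == frozenset({2})
        assert sg.induced_edges == frozenset()

    def test_path_graph_root_middle_k1(self, path_graph):
        sg = extract_khop_subgraph(path_graph, 2, 1)
        assert sg.member_nodes == frozenset({1, 2, 3})
        assert sg.induced_edges == frozenset({(1, 2), (2, 3)})

    def test_k_at_least_diameter_gives_component(self, path_graph):
        sg = extract_khop_subgraph(path_graph, 0, 10)
        assert sg.member_nodes == frozenset(range(5))

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        import networkx as nx

        for _ in range(10):
            g = random_graph(rng, int(rng.integers(8, 15)), k=2)
            nxg = nx.Graph(list(g.edge_set))
            nxg.add_nodes_from(range(g.n_nodes))
            root = int(rng.integers(g.n_nodes))
            k = int(rng.integers(0, 4))
            expected = {
                n for n, d in nx.single_source_shortest_path_length(nxg, root, cutoff=k).items()
            }
            assert extract_khop_subgraph(g, root, k).member_nodes == expected


def structural_oracle(graph: BrainGraph, states: np.ndarray, params, prefix, cfg):
    """Independent per-root loop: run the member-masked GNN one root at a
    time on the induced subgraph and read out the root."""
    n = graph.n_nodes
    masks = khop_masks(graph.adjacency, cfg.k_hops)
    out = np.zeros((n, cfg.hidden_dim))
    for r in range(n):
        members = np.nonzero(masks[r])[0]
        sub_a = graph.adjacency[np.ix_(members, members)]
        h = states[members]
        for g in range(cfg.gnn_layers):
            w_self = params[f"{prefix}.gnn{g}.Wself"].data
            w_nbr = params[f"{prefix}.gnn{g}.Wnbr"].data
            b = params[f"{prefix}.gnn{g}.b"].data
            h = np.maximum(h @ w_self + (sub_a @ h) @ w_nbr + b, 0.0)
        out[r] = h[list(members).index(r)]
    return out


def plain_transformer_layer(x, params, prefix, cfg):
    """Dense self-attention reference that never sees the graph: the
    structural branch is each node's own feature through the extractor MLP."""
    s = x.copy()
    for g in range(cfg.gnn_layers):
        s = np.maximum(
            s @ params[f"{prefix}.gnn{g}.Wself"].data + params[f"{prefix}.gnn{g}.b"].data,
            0.0,
        )
    n, d = x.shape
    nh, dh = cfg.n_heads, d // cfg.n_heads

    def lin(v, name):
        return v @ params[f"{prefix}.{name}.W"].data + params[f"{prefix}.{name}.b"].data

    q = lin(s, "Wq").reshape(n, nh, dh).transpose(1, 0, 2)
    k = lin(s, "Wk").reshape(n, nh, dh).transpose(1, 0, 2)
    v = lin(x, "Wv").reshape(n, nh, dh).transpose(1, 0, 2)
    scores = q @ k.transpose(0, 2, 1) / np.sqrt(dh)
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    attn = e / e.sum(axis=-1, keepdims=True)
    ctx = lin((attn @ v).transpose(1, 0, 2).reshape(n, d), "Wo")

    def ln(v, name):
        mu = v.mean(-1, keepdims=True)
        var = ((v - mu) ** 2).mean(-1, keepdims=True)
        return (v - mu) / np.sqrt(var + 1e-5) * params[f"{prefix}.{name}.gamma"].data + params[
            f"{prefix}.{name}.beta"
        ].data

    h = ln(x + ctx, "ln1")
    ff = np.maximum(lin(h, "ffn.fc1"), 0.0) @ params[f"{prefix}.ffn.fc2.W"].data + params[
        f"{prefix}.ffn.fc2.b"
    ].data
    return ln(h + ff, "ln2")


def plain_transformer_encoder(graph, params, prefix, cfg):
    x = graph.node_features @ params[f"{prefix}.in_proj.W"].data + params[
        f"{prefix}.in_proj.b"
    ].data
    for layer in range(cfg.n_layers):
        x = plain_transformer_layer(x, params, f"{prefix}.layer{layer}", cfg)
    return x.mean(axis=0)


class TestStructuralEmbedding:
    def test_matches_per_root_loop_oracle(self, rng):
        from atlasfuse.autodiff import Tensor
        from atlasfuse.sat import _structure_cache, _subgraph_gnn

        for trial in range(5):
            g = random_graph(rng, 8, k=3)
            cfg = tiny_cfg(k_hops=int(rng.integers(0, 3)), hidden_dim=4)
            params = sat_params(rng, 8, cfg, "enc")
            states = rng.standard_normal((8, 4))
            adj_t, mask_t = _structure_cache(g, cfg)
            h = Tensor(states).reshape(1, 8, -1) * mask_t
            got = _subgraph_gnn(h, adj_t, mask_t, params, "enc.layer0", cfg).data
            want = structural_oracle(g, states, params, "enc.layer0", cfg)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_isomorphic_subgraphs_same_embedding(self):
        # path 0-1-2-3-4: nodes 1 and 3 have isomorphic 1-hop subgraphs
        adj = np.zeros((5, 5))
        for i in range(4):
            adj[i, i + 1] = adj[i + 1, i] = 0.5
        feats = np.ones((5, 3))  # identical member features
        g = BrainGraph("s", AtlasSpec.generic("p5", 5), adj, feats, 0)
        cfg = tiny_cfg(k_hops=1, hidden_dim=4)
        rng = np.random.default_rng(0)
        params = sat_params(rng, 3, cfg, "enc")
        from atlasfuse.autodiff import Tensor
        from atlasfuse.sat import _structure_cache, _subgraph_gnn

        adj_t, mask_t = _structure_cache(g, cfg)
        states = np.ones((5, 4))
        h = Tensor(states).reshape(1, 5, -1) * mask_t
        emb = _subgraph_gnn(h, adj_t, mask_t, params, "enc.layer0", cfg).data
        np.testing.assert_allclose(emb[1], emb[3], atol=1e-12)


class TestEncoder:
    def test_single_node_attention_is_one(self):
        g = BrainGraph("s", AtlasSpec.generic("one", 1), np.zeros((1, 1)), np.ones((1, 1)), 0)
        cfg = tiny_cfg(hidden_dim=4)
        params = sat_params(np.random.default_rng(0), 1, cfg, "enc")
        _, attns = encode_graph(g, cfg, params, "enc", rng=None)
        np.testing.assert_allclose(attns[0], 1.0)

    def test_k0_equals_plain_transformer(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 12))
            g = random_graph(rng, n, k=3)
            cfg = tiny_cfg(k_hops=0, n_layers=2, hidden_dim=8, n_heads=2)
            params = sat_params(rng, n, cfg, "enc")
            got, _ = encode_graph(g, cfg, params, "enc", rng=None)
            want = plain_transformer_encoder(g, params, "enc", cfg)
            np.testing.assert_allclose(got.data, want, atol=1e-5)

    def test_attention_rows_normalized(self, rng):
        g = random_graph(rng, 10, k=3)
        cfg = tiny_cfg(n_layers=2, hidden_dim=8)
        params = sat_params(rng, 10, cfg, "enc")
        _, attns = encode_graph(g, cfg, params, "enc", rng=None)
        for a in attns:
            assert (a >= 0).all()
            np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-6)

    def test_permutation_invariance_of_graph_embedding(self, rng):
        for _ in range(5):
            n = 9
            g = random_graph(rng, n, k=3)
            cfg = tiny_cfg(k_hops=1, n_layers=2, hidden_dim=8)
            params = sat_params(rng, n, cfg, "enc")
            base, _ = encode_graph(g, cfg, params, "enc", rng=None)
            perm = rng.permutation(n)
            # consistent relabeling: adjacency permuted on both axes, each
            # node's feature vector travels with the node (row permutation)
            gp = BrainGraph(
                g.subject_id,
                g.atlas,
                g.adjacency[np.ix_(perm, perm)],
                g.node_features[perm],
                g.label,
            )
            permuted, _ = encode_graph(gp, cfg, params, "enc", rng=None)
            np.testing.assert_allclose(base.data, permuted.data, atol=1e-5)

    def test_evaluation_mode_bit_identical(self, rng):
        g = random_graph(rng, 8, k=3)
        cfg = tiny_cfg(dropout_rate=0.3, n_layers=2, hidden_dim=8)
        params = sat_params(rng, 8, cfg, "enc")
        a, _ = encode_graph(g, cfg, params, "enc", rng=None)
        b, _ = encode_graph(g, cfg, params, "enc", rng=None)
        assert (a.data == b.data).all()

    def test_identical_node_states_mean_readout(self, rng):
        # fully-disconnected graph with identical features: every node is
        # processed identically, so the mean readout equals any node's state
        n = 6
        g = BrainGraph(
            "s", AtlasSpec.generic("d6", n), np.zeros((n, n)), np.ones((n, 4)), 0
        )
        cfg = tiny_cfg(k_hops=1, hidden_dim=4)
        params = sat_params(rng, 4, cfg, "enc")
        emb, attns = encode_graph(g, cfg, params, "enc", rng=None)
        assert np.isfinite(emb.data).all()
        # uniform attention across identical keys
        np.testing.assert_allclose(attns[0], 1.0 / n, atol=1e-8)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SATConfig(hidden_dim=10, n_heads=4)
        with pytest.raises(ValueError):
            SATConfig(dropout_rate=1.0)
        assert SATConfig().n_layers == 3
        assert SATConfig().dropout_rate == pytest.approx(0.3)
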