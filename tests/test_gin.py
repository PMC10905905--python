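"""GIN encoder: hand-computed forward pass, invariances, checkpointing."""

import numpy as np
import pytest

from moldescpred import (
    GINConfig,
    GINParameters,
    GraphBatch,
    MolecularGraph,
    featurize_molecule,
    gin_encode,
    gin_forward,
    load_checkpoint,
    save_checkpoint,
)


def permute_graph(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Relabel nodes: node j becomes node perm[j]."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return MolecularGraph(
        node_features=g.node_features[inv],
        edge_index=perm[g.edge_index] if g.num_edges else g.edge_index,
        edge_features=g.edge_features,
        smiles=g.smiles,
    )


@pytest.fixture
def gin(tiny_gin_config):
    return GINParameters(tiny_gin_config, seed=3)


class TestForwardPass:
    def test_hand_computed_two_node_graph(self):
        """Identity-weight forward pass checked against explicit arithmetic."""
        cfg = GINConfig(node_feature_dim=2, edge_feature_dim=2, num_layers=1,
                        hidden_dim=2, representation_dim=2, dropout_rate=0.0)
        gin = GINParameters(cfg, seed=0)
        eye = np.eye(2)
        zero = np.zeros(2)
        for k in gin.params:
            if k.endswith(".W") or k.endswith(".W1") or k.endswith(".W2"):
                gin.params[k].value = eye.copy()
            elif k == "r.a":
                gin.params[k].value = np.array(0.25)
            else:
                gin.params[k].value = zero.copy()

        v = np.array([[1.0, -1.0], [2.0, 0.0]])
        e = np.array([[0.5, 0.5], [0.5, 0.5]])
        graph = MolecularGraph(v, np.array([[0, 1], [1, 0]]), e, smiles="XX")

        # oracle: explicit equations with plain numpy
        h0 = np.maximum(v, 0)                      # initial node embedding
        he = e                                     # linear edge embedding
        msg_to_0 = np.maximum(h0[1] + he[0], 0)    # neighbour 1 -> node 0
        msg_to_1 = np.maximum(h0[0] + he[1], 0)
        u = np.stack([h0[0] + msg_to_0, h0[1] + msg_to_1])
        h1 = np.maximum(u, 0) @ eye                # psi: ReLU hidden, linear out
        hg = h1.mean(axis=0)
        expected_rep = np.where(hg > 0, hg, 0.25 * hg)

        emb = gin_forward(graph, gin)
        np.testing.assert_allclose(emb.pooled, hg, atol=1e-12)
        np.testing.assert_allclose(emb.representation, expected_rep, atol=1e-12)

    def test_single_node_graph_reduces_to_mlp(self, tiny_gin_config, gin, schema):
        """With no neighbours, each layer is psi(h) and pooling is the node itself."""
        g = featurize_molecule("C", schema)
        emb = gin_forward(g, gin)
        p = gin.params
        h = np.maximum(g.node_features @ p["phi_n.W"].value + p["phi_n.b"].value, 0)
        for l in range(1, tiny_gin_config.num_layers + 1):
            a = np.maximum(h @ p[f"psi{l}.W1"].value + p[f"psi{l}.b1"].value, 0)
            h = a @ p[f"psi{l}.W2"].value + p[f"psi{l}.b2"].value
            if l < tiny_gin_config.num_layers:
                h = np.maximum(h, 0)
        np.testing.assert_allclose(emb.pooled, h[0], atol=1e-10)

    def test_permutation_invariance(self, gin, schema, rng):
        """Node relabeling changes the representation by < 1e-5 over 50 draws."""
        smiles = ["CC(=O)Oc1ccccc1C(=O)O", "CCN(CC)c1ccncc1", "OCC(O)COc1ccoc1"]
        worst = 0.0
        for smi in smiles:
            g = featurize_molecule(smi, schema)
            base = gin_forward(g, gin).representation
            for _ in range(50):
                perm = rng.permutation(g.num_nodes)
                rep = gin_forward(permute_graph(g, perm), gin).representation
                worst = max(worst, np.abs(rep - base).max())
        assert worst < 1e-5

    def test_locality_beyond_l_hops(self, tiny_gin_config, gin, schema):
        """Perturbing a node > L hops away leaves a node's final embedding fixed."""
        g = featurize_molecule("CCCCCCCC", schema)  # path graph, 8 nodes
        base = gin_forward(g, gin).node_embeddings[-1][0]
        far = MolecularGraph(g.node_features.copy(), g.edge_index,
                             g.edge_features, g.smiles)
        far.node_features[7] = 1.0 - far.node_features[7]  # 7 hops from node 0
        pert = gin_forward(far, gin).node_embeddings[-1][0]
        np.testing.assert_array_equal(base, pert)
        near = MolecularGraph(g.node_features.copy(), g.edge_index,
                              g.edge_features, g.smiles)
        near.node_features[2] = 1.0 - near.node_features[2]  # within 3 hops
        assert np.abs(gin_forward(near, gin).node_embeddings[-1][0] - base).max() > 0

    def test_deterministic_mode_bit_identical(self, gin, schema):
        g = featurize_molecule("c1ccc(Cl)cc1CCO", schema)
        a = gin_forward(g, gin).representation
        b = gin_forward(g, gin).representation
        np.testing.assert_array_equal(a, b)

    def test_symmetric_graph_pooling_equals_node_embedding(self, gin, schema):
        """Benzene: all final node embeddings equal, so pooling returns them."""
        g = featurize_molecule("c1ccccc1", schema)
        emb = gin_forward(g, gin)
        final = emb.node_embeddings[-1]
        np.testing.assert_allclose(final, np.broadcast_to(final[0], final.shape),
                                   atol=1e-10)
        np.testing.assert_allclose(emb.pooled, final[0], atol=1e-10)

    def test_batch_matches_single(self, gin, schema, small_graphs):
        batch = GraphBatch.from_graphs(small_graphs)
        reps, _, _ = gin_encode(batch, gin)
        for i, g in enumerate(small_graphs):
            np.testing.assert_allclose(
                reps.value[i], gin_forward(g, gin).representation, atol=1e-10
            )

    def test_stochastic_seeded_reproducible(self, gin, schema):
        g = featurize_molecule("CCO", schema)
        a = gin_forward(g, gin, stochastic=True, rng=np.random.default_rng(5))
        b = gin_forward(g, gin, stochastic=True, rng=np.random.default_rng(5))
        c = gin_forward(g, gin, stochastic=True, rng=np.random.default_rng(6))
        np.testing.assert_array_equal(a.representation, b.representation)
        assert np.abs(a.representation - c.representation).max() > 0

    def test_dimension_mismatch_raises(self, gin, schema):
        bad = MolecularGraph(np.ones((2, 3)), np.array([[0, 1], [1, 0]]),
                             np.ones((2, 4)), "XX")
        with pytest.raises(ValueError):
            gin_forward(bad, gin)

    def test_literal_message_mode_differs(self, tiny_gin_config, schema):
        """The printed-form switch (centre-node message) changes the output."""
        cfg_lit = GINConfig(**{**tiny_gin_config.to_dict(), "literal_messages": True})
        g = featurize_molecule("CCO", schema)
        a = gin_forward(g, GINParameters(tiny_gin_config, seed=3)).representation
        b = gin_forward(g, GINParameters(cfg_lit, seed=3)).representation
        assert np.abs(a - b).max() > 0


class TestParameters:
    def closed_form(self, cfg: GINConfig) -> int:
        h, r = cfg.hidden_dim, cfg.representation_dim
        n = (cfg.node_feature_dim + 1) * h + (cfg.edge_feature_dim + 1) * h
        n += cfg.num_layers * 2 * (h + 1) * h
        n += (h + 1) * r + 1  # projection + PReLU slope
        return n

    def test_count_matches_closed_form(self, tiny_gin_config):
        gin = GINParameters(tiny_gin_config, seed=0)
        assert gin.count_parameters() == self.closed_form(tiny_gin_config)

    def test_full_width_count_matches_closed_form(self, schema):
        cfg = GINConfig(node_feature_dim=schema.node_feature_dim,
                        edge_feature_dim=schema.edge_feature_dim)
        assert GINParameters(cfg, seed=0).count_parameters() == self.closed_form(cfg)

    def test_extra_layer_adds_exactly_one_psi_block(self, tiny_gin_config):
        cfg4 = GINConfig(**{**tiny_gin_config.to_dict(), "num_layers": 4})
        h = tiny_gin_config.hidden_dim
        delta = (GINParameters(cfg4, 0).count_parameters()
                 - GINParameters(tiny_gin_config, 0).count_parameters())
        assert delta == 2 * (h + 1) * h

    def test_zero_layer_config(self, tiny_gin_config):
        cfg0 = GINConfig(**{**tiny_gin_config.to_dict(), "num_layers": 0})
        gin = GINParameters(cfg0, 0)
        assert gin.count_parameters() == self.closed_form(cfg0)
        assert not any(k.startswith("psi") for k in gin.params)


class TestCheckpoint:
    def test_round_trip_bit_identical(self, tiny_gin_config, gin, tmp_path):
        p = tmp_path / "ckpt.npz"
        save_checkpoint(p, gin, extra_arrays={"note": np.arange(3.0)})
        back, extra, manifest = load_checkpoint(p, expected_config=tiny_gin_config)
        for k, v in gin.state_dict().items():
            np.testing.assert_array_equal(back.state_dict()[k], v)
        np.testing.assert_array_equal(extra["note"], np.arange(3.0))
        assert manifest["config"]["hidden_dim"] == tiny_gin_config.hidden_dim

    def test_architecture_mismatch_refused_with_diff(self, tiny_gin_config, gin, tmp_path):
        p = tmp_path / "ckpt.npz"
        save_checkpoint(p, gin)
        wrong = GINConfig(**{**tiny_gin_config.to_dict(), "hidden_dim": 32})
        with pytest.raises(ValueError, match="hidden_dim"):
            load_checkpoint(p, expected_config=wrong)
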