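"""Graph assembly: edge weights, merging, and feature standardization."""

import numpy as np
import pytest

from vgn.graph_builder import (
    GraphFeatureScaler,
    build_bscan_graph,
    edge_weight,
    merge_graphs,
    standardize_features,
)
from vgn.types import VesselNode

from conftest import make_graph, make_node

PITCH = 3e-6


class TestEdgeWeight:
    def test_lateral_millimeter_distances(self):
        w = edge_weight(make_node(1.0e-3), make_node(2.0e-3))
        assert w == pytest.approx(1000.0)

    def test_adjacent_bscans_one_pitch_apart(self):
        w = edge_weight(make_node(0.5e-3, y=0.0), make_node(0.5e-3, y=PITCH))
        assert w == pytest.approx(1.0 / PITCH)

    def test_colocated_nodes_clamped_to_pixel_pitch(self):
        w = edge_weight(make_node(1e-3), make_node(1e-3))
        assert w == pytest.approx(1.0 / PITCH)
        assert np.isfinite(w)

    def test_self_loop_rejected(self):
        node = make_node(1e-3)
        with pytest.raises(ValueError, match="self-loop"):
            edge_weight(node, node)

    def test_monotone_decreasing_with_distance(self):
        base = make_node(0.0)
        dists = np.linspace(10e-6, 2e-3, 25)
        weights = [edge_weight(base, make_node(d)) for d in dists]
        assert all(a > b for a, b in zip(weights, weights[1:]))


def five_nodes(spacing=100e-6, y=0.0):
    return [make_node(i * spacing + 0.5e-3, y=y) for i in range(5)]


class TestBuildBScanGraph:
    def test_five_nodes_ten_edges(self):
        g = build_bscan_graph(five_nodes(), y_index=0)
        assert g.n_nodes == 5
        assert len(g.edges) == 10

    def test_equally_spaced_harmonic_weights(self):
        d = 100e-6
        g = build_bscan_graph(five_nodes(spacing=d), y_index=0)
        # all 10 pairs enumerated by hand: weight 1/(k*d) for |i-j| = k
        for i, j, w in g.edges:
            assert w == pytest.approx(1.0 / (abs(i - j) * d))

    def test_padding_nodes_still_complete(self):
        nodes = five_nodes()[:3] + [
            VesselNode.padding((1.5e-3, 0.0)),
            VesselNode.padding((1.5e-3, 0.0)),
        ]
        g = build_bscan_graph(nodes, y_index=0)
        assert g.n_nodes == 5 and len(g.edges) == 10
        assert g.valid.sum() == 3
        assert np.all(g.weights[np.triu_indices(5, 1)] > 0)

    def test_wrong_slot_count_rejected(self):
        with pytest.raises(ValueError, match="exactly 5"):
            build_bscan_graph(five_nodes()[:4], y_index=0)


class TestMergeGraphs:
    def graphs_for(self, n_bscans, spacing=100e-6):
        return [
            build_bscan_graph(
                [make_node(i * spacing + 1e-4, y=k * PITCH) for i in range(5)],
                y_index=k,
            )
            for k in range(n_bscans)
        ]

    def test_41_bscans_yield_205_nodes_20910_edges(self):
        merged = merge_graphs(self.graphs_for(41))
        assert merged.n_nodes == 205
        assert merged.n_edges == 20910
        assert np.allclose(merged.weights, merged.weights.T)
        iu = np.triu_indices(205, 1)
        assert np.all(merged.weights[iu] > 0)

    def test_single_graph_merge_is_identity(self):
        g = self.graphs_for(1)[0]
        merged = merge_graphs([g])
        assert np.array_equal(merged.node_features, g.node_features)
        assert np.allclose(merged.weights, g.weights)

    def test_coplanar_nodes_ten_steps_apart(self):
        graphs = self.graphs_for(11)
        merged = merge_graphs(graphs)
        # same x (slot 0), B-scans 0 and 10: Euclidean distance 30 um
        assert merged.weights[0, 50] == pytest.approx(1.0 / 30e-6)

    def test_nonconsecutive_indices_rejected(self):
        graphs = self.graphs_for(3)
        with pytest.raises(ValueError, match="consecutive"):
            merge_graphs([graphs[0], graphs[2]])

    def test_merge_preserves_node_features_roundtrip(self):
        graphs = self.graphs_for(5)
        merged = merge_graphs(graphs)
        for k, g in enumerate(graphs):
            assert np.array_equal(
                merged.node_features[5 * k:5 * (k + 1)], g.node_features
            )

    def test_weights_match_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        graphs = [
            build_bscan_graph(
                [make_node(x, y=k * PITCH) for x in rng.uniform(0, 3e-3, 5)],
                y_index=k,
            )
            for k in range(2)
        ]
        merged = merge_graphs(graphs)
        nodes = merged.nodes
        for i in range(10):
            for j in range(10):
                if i == j:
                    assert merged.weights[i, j] == 0
                else:
                    assert merged.weights[i, j] == pytest.approx(
                        edge_weight(nodes[i], nodes[j])
                    )


class TestGraphFeatureScaler:
    def test_identical_graphs_standardize_to_zero(self):
        g = make_graph(np.array([[0.0, 0], [1e-3, 0], [2e-3, 0]]))
        out, _ = standardize_features([g, g])
        assert np.allclose(out[0].node_features, 0.0)

    def test_known_mean_and_sd(self):
        feats_a = np.full((2, 7), 3.0)
        feats_b = np.full((2, 7), 7.0)  # mean 5, sd 2
        ga = make_graph(np.array([[0.0, 0], [1e-3, 0]]), features=feats_a)
        gb = make_graph(np.array([[0.0, 0], [1e-3, 0]]), features=feats_b)
        scaler = GraphFeatureScaler().fit([ga, gb])
        g9 = make_graph(np.array([[0.0, 0], [1e-3, 0]]), features=np.full((2, 7), 9.0))
        out = scaler.transform([g9])[0]
        assert np.allclose(out.node_features, 2.0)

    def test_heldout_transform_uses_training_statistics(self):
        rng = np.random.default_rng(0)
        train = [
            make_graph(np.array([[0.0, 0], [1e-3, 0]]),
                       features=rng.normal(5, 2, (2, 7)))
            for _ in range(20)
        ]
        scaler = GraphFeatureScaler().fit(train)
        held = make_graph(np.array([[0.0, 0], [1e-3, 0]]),
                          features=rng.normal(50, 9, (2, 7)))
        out = scaler.transform([held])[0]
        expected = (held.node_features - scaler.mean_) / scaler.scale_
        assert np.allclose(out.node_features, expected)
        assert np.abs(out.node_features).max() > 3  # clearly not self-standardized

    def test_zero_variance_feature_warns_and_uses_unit_scale(self):
        g = make_graph(np.array([[0.0, 0], [1e-3, 0]]), features=np.ones((2, 7)))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            scaler = GraphFeatureScaler().fit([g])
        assert np.all(scaler.scale_ == 1.0)

    def test_padding_and_missing_features_become_zero(self):
        feats = np.ones((3, 7))
        feats[0, 0] = np.nan  # missing temporal feature on a valid node
        g = make_graph(np.array([[0.0, 0], [1e-3, 0], [2e-3, 0]]), features=feats)
        g.valid[2] = False
        rng = np.random.default_rng(1)
        train = [make_graph(np.array([[0.0, 0], [1e-3, 0]]),
                            features=rng.normal(size=(2, 7))) for _ in range(5)]
        scaler = GraphFeatureScaler().fit(train)
        out = scaler.transform([g])[0]
        assert out.node_features[0, 0] == 0.0
        assert np.all(out.node_features[2] == 0.0)
        assert np.isfinite(out.node_features).all()

    def test_unfitted_transform_rejected(self):
        with pytest.raises(RuntimeError, match="fitted"):
            GraphFeatureScaler().transform([])
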