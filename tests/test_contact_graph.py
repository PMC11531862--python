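import numpy as np
import pytest

from mtloc.contact_graph import (EdgeFeatureConfig, ResidueGraph,
                                 SyntheticEmbeddingProvider,
                                 build_contact_map, build_graph,
                                 compute_edge_features, init_node_features,
                                 load_graph, save_graph)
from mtloc.io_formats import FormatError

from .conftest import random_backbone


def brute_force_contacts(coords, threshold):
    n = coords.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(n)
             if i != j and np.linalg.norm(coords[i] - coords[j]) <= threshold]
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def test_contact_map_matches_brute_force_on_100_backbones():
    rng = np.random.default_rng(12)
    for _ in range(100):
        n = int(rng.integers(2, 40))
        coords = random_backbone(rng, n)
        got = build_contact_map(coords, 4.5)
        np.testing.assert_array_equal(got, brute_force_contacts(coords, 4.5))


def test_contact_threshold_is_inclusive():
    coords = np.array([[0.0, 0, 0], [4.5, 0, 0], [100.0, 0, 0]])
    edges = build_contact_map(coords, 4.5)
    np.testing.assert_array_equal(edges, [[0, 1], [1, 0]])


def test_contact_monotone_in_threshold():
    rng = np.random.default_rng(3)
    coords = random_backbone(rng, 30)
    sets = []
    for thr in (4.0, 4.5, 6.0, 8.0, 10.0):
        sets.append({tuple(e) for e in build_contact_map(coords, thr)})
    for smaller, larger in zip(sets, sets[1:]):
        assert smaller <= larger


def test_single_residue_and_empty_contact_sets():
    assert build_contact_map(np.zeros((1, 3))).shape == (0, 2)
    far = np.array([[0.0, 0, 0], [50.0, 0, 0]])
    assert build_contact_map(far, 4.5).shape == (0, 2)


def test_edge_feature_dimension():
    assert EdgeFeatureConfig().dim == 42


def test_edge_features_translation_invariant():
    rng = np.random.default_rng(7)
    coords = random_backbone(rng, 20)
    edges = build_contact_map(coords, 6.0)
    base = compute_edge_features(coords, edges)
    shifted = compute_edge_features(coords + np.array([13.0, -4.0, 99.0]), edges)
    np.testing.assert_allclose(base, shifted, atol=1e-9)


def test_edge_features_hand_computed_two_residues():
    coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
    edges = build_contact_map(coords, 4.5)
    feats = compute_edge_features(coords, edges)
    # edge 0 -> 1: distance 3, displacement (3,0,0)
    row = feats[0]
    assert row[0] == pytest.approx(3.0)
    # sin/cos of 3*freq for x, of 0 for y/z, freqs 1, .5, .25, .125
    expected_trig = []
    for axis_val in (3.0, 0.0, 0.0):
        for f in (1.0, 0.5, 0.25, 0.125):
            expected_trig.append(np.sin(axis_val * f))
        for f in (1.0, 0.5, 0.25, 0.125):
            expected_trig.append(np.cos(axis_val * f))
    np.testing.assert_allclose(row[1:25], expected_trig, atol=1e-12)
    # k-NN block: only one neighbour exists -> first slot (3,0,0), rest zero
    np.testing.assert_allclose(row[25:28], [3.0, 0.0, 0.0])
    np.testing.assert_allclose(row[28:40], 0.0)
    # distance sums for both endpoints
    np.testing.assert_allclose(row[40:42], [3.0, 3.0])


def test_nearest_neighbour_ties_break_by_lower_index():
    # residues 1 and 2 equidistant from 0; k=1 must pick residue 1
    coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.0, 2.0, 0], [9.0, 9, 9]])
    cfg = EdgeFeatureConfig(n_neighbours=1)
    edges = np.array([[0, 3]])
    feats = compute_edge_features(coords, edges, cfg)
    knn_start = 1 + 6 * cfg.n_frequencies
    np.testing.assert_allclose(feats[0, knn_start:knn_start + 3], [2.0, 0, 0])


def test_init_node_features_strips_flanks_and_truncates():
    class Flanked:
        dim = 4
        flank_rows = (1, 1)

        def embed(self, sequence):
            return np.arange((len(sequence) + 2) * 4, dtype=float).reshape(-1, 4)

    mat = init_node_features(Flanked(), "ACD")
    assert mat.shape == (3, 4)
    np.testing.assert_allclose(mat[0], [4, 5, 6, 7])  # first flank removed


def test_init_node_features_rejects_short_provider():
    class Short:
        dim = 2
        flank_rows = (0, 0)

        def embed(self, sequence):
            return np.zeros((len(sequence) - 1, 2))

    with pytest.raises(FormatError):
        init_node_features(Short(), "ACDE")


def test_synthetic_provider_deterministic_and_sequence_sensitive():
    prov = SyntheticEmbeddingProvider(dim=8, seed=3)
    a1, a2 = prov.embed("ACDE"), prov.embed("ACDE")
    np.testing.assert_array_equal(a1, a2)
    assert not np.allclose(a1, prov.embed("ACDF"))
    assert a1.shape == (4, 8)


def test_build_graph_shapes_and_validation():
    rng = np.random.default_rng(1)
    coords = random_backbone(rng, 10)
    graph = build_graph("A" * 10, coords, SyntheticEmbeddingProvider(dim=6),
                        threshold=6.0, protein_id="p")
    assert graph.n_nodes == 10
    assert graph.node_feats.shape == (10, 6)
    assert graph.edge_feats.shape == (graph.n_edges, 42)


def test_residue_graph_rejects_self_edges_and_asymmetry():
    nf = np.zeros((3, 2))
    xyz = np.zeros((3, 3))
    with pytest.raises(FormatError, match="self-edges"):
        ResidueGraph(nf, np.array([[1, 1]]), np.zeros((1, 42)), xyz)
    with pytest.raises(FormatError, match="symmetric"):
        ResidueGraph(nf, np.array([[0, 1]]), np.zeros((1, 42)), xyz)


def test_graph_cache_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    coords = random_backbone(rng, 8)
    graph = build_graph("A" * 8, coords, SyntheticEmbeddingProvider(dim=4),
                        threshold=6.0, protein_id="p8")
    path = tmp_path / "p8.npz"
    save_graph(graph, path)
    back = load_graph(path)
    assert back.protein_id == "p8"
    np.testing.assert_array_equal(back.edge_index, graph.edge_index)
    np.testing.assert_allclose(back.node_feats, graph.node_feats)
    np.testing.assert_allclose(back.edge_feats, graph.edge_feats)
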