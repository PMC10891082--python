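import networkx as nx
import numpy as np
import pytest

import graphser as g
from graphser.features import FEATURE_NAMES, modularity_of_partition


def complete(n):
    return np.ones((n, n)) - np.eye(n)


def path3():
    return np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)


def k4_minus_edge():
    a = complete(4)
    a[0, 1] = a[1, 0] = 0
    return a


def two_triangles():
    a = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1
    return a


WEIGHTED_PAIR = np.array([[0.0, 0.5], [0.5, 0.0]])


class TestCanonicalValues:
    @pytest.mark.parametrize(
        "func, a, expected",
        [
            (g.total_degree, complete(3), 6.0),
            (g.total_degree, np.zeros((3, 3)), 0.0),
            (g.total_degree, WEIGHTED_PAIR, 1.0),
            (g.global_clustering, complete(3), 1.0),
            (g.global_clustering, path3(), 0.0),
            (g.global_clustering, k4_minus_edge(), 5 / 6),
            (g.density, complete(3), 1.0),
            (g.density, path3(), 2 / 3),
            (g.density, np.zeros((4, 4)), 0.0),
            (g.averaged_value, complete(3), 6 / 9),
            (g.averaged_value, np.zeros((3, 3)), 0.0),
            (g.averaged_value, WEIGHTED_PAIR, 0.25),
            (g.graph_energy, complete(3), 6.0),  # spectrum {2, -1, -1}
            (g.graph_energy, np.zeros((5, 5)), 0.0),
        ],
    )
    def test_feature_examples(self, func, a, expected):
        assert func(a) == pytest.approx(expected)

    def test_modularity_of_two_disjoint_triangles(self):
        q, communities = g.best_modularity(two_triangles())
        assert q == pytest.approx(0.5)
        assert sorted(map(sorted, communities)) == [[0, 1, 2], [3, 4, 5]]

    def test_single_community_partition_has_zero_modularity(self):
        a = two_triangles()
        assert modularity_of_partition(a, [set(range(6))]) == pytest.approx(0.0)

    def test_zero_weight_graph_modularity_convention(self):
        q, communities = g.best_modularity(np.zeros((4, 4)))
        assert q == 0.0
        assert communities == [{0}, {1}, {2}, {3}]


class TestInvariants:
    def test_energy_equals_trace_of_square(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 15))
            a = rng.uniform(0, 1, (n, n))
            a = np.triu(a, 1)
            a = a + a.T
            assert g.graph_energy(a) == pytest.approx(np.trace(a @ a), abs=1e-8)

    def test_binary_energy_equals_twice_edge_count(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 20))
            a = np.triu((rng.uniform(size=(n, n)) < 0.4).astype(float), 1)
            a = a + a.T
            assert g.graph_energy(a) == pytest.approx(a.sum(), abs=1e-8)

    def test_clustering_and_density_bounded_for_binary_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            a = np.triu((rng.uniform(size=(n, n)) < 0.5).astype(float), 1)
            a = a + a.T
            assert 0.0 <= g.global_clustering(a) <= 1.0
            assert 0.0 <= g.density(a) <= 1.0

    def test_all_features_permutation_invariant(self, rng):
        a = np.triu(rng.uniform(0, 1, (10, 10)) * (rng.uniform(size=(10, 10)) < 0.5), 1)
        a = a + a.T
        perm = rng.permutation(10)
        b = a[np.ix_(perm, perm)]
        for func in (g.total_degree, g.global_clustering, g.density,
                     g.averaged_value, g.graph_energy):
            assert func(b) == pytest.approx(func(a), abs=1e-10)
        assert g.best_modularity(b)[0] == pytest.approx(g.best_modularity(a)[0], abs=1e-10)

    def test_modularity_self_consistent_and_nonnegative_vs_trivial(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 16))
            a = np.triu((rng.uniform(size=(n, n)) < 0.35).astype(float), 1)
            a = a + a.T
            if a.sum() == 0:
                continue
            q, communities = g.best_modularity(a)
            assert q == pytest.approx(modularity_of_partition(a, communities), abs=1e-12)
            assert q >= modularity_of_partition(a, [set(range(n))]) - 1e-12

    def test_modularity_formula_matches_networkx(self, rng):
        """Independent cross-check of the Q formula against nx.community.modularity."""
        for _ in range(10):
            n = int(rng.integers(4, 14))
            a = np.triu(rng.uniform(0, 1, (n, n)) * (rng.uniform(size=(n, n)) < 0.5), 1)
            a = a + a.T
            if a.sum() == 0:
                continue
            graph = nx.from_numpy_array(a)
            nodes = list(range(n))
            half = [set(nodes[: n // 2]), set(nodes[n // 2 :])]
            expected = nx.community.modularity(graph, half, weight="weight")
            assert modularity_of_partition(a, half) == pytest.approx(expected, abs=1e-10)

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(g.ParameterError):
            g.total_degree(np.array([[0.0, 1.0], [0.5, 0.0]]))  # asymmetric
        with pytest.raises(g.ParameterError):
            g.graph_energy(np.array([[1.0, 0.0], [0.0, 0.0]]))  # nonzero diagonal


class TestUtteranceFeatures:
    def test_eleven_finite_named_values(self, tiny_corpus):
        _, utterances = tiny_corpus
        feats = g.utterance_features(utterances[0])
        assert sorted(feats.values) == sorted(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in feats.values.values())

    def test_positive_scaling_leaves_structural_features_unchanged(self, tiny_corpus):
        _, utterances = tiny_corpus
        utt = utterances[0]
        scaled = g.Utterance(utt.utterance_id, 0.37 * utt.samples,
                             utt.sample_rate_hz, utt.speaker_id, utt.emotion)
        f1 = g.utterance_features(utt)
        f2 = g.utterance_features(scaled)
        for name in g.STRUCTURAL_FEATURES:
            assert f2.values[name] == pytest.approx(f1.values[name], abs=1e-9)

    def test_short_utterance_error_names_it(self):
        utt = g.Utterance("too_short", np.sin(np.arange(4000) / 10.0), 16000,
                          "spk", "sad")
        with pytest.raises(g.DegenerateSignalError, match="too_short"):
            g.utterance_features(utt)

    def test_extractor_skips_degenerate_and_keeps_the_rest(self, tiny_corpus):
        _, utterances = tiny_corpus
        bad = g.Utterance("bad", np.sin(np.arange(4000) / 10.0), 16000, "s", "e")
        extractor = g.GraphFeatureExtractor()
        out = extractor.fit().transform([utterances[0], bad, utterances[1]])
        assert len(out) == 2
        assert extractor.skipped_ == ["bad"]

    def test_sklearn_param_interface(self):
        extractor = g.GraphFeatureExtractor(stat_window=4000)
        assert extractor.get_params()["stat_window"] == 4000
        clone = extractor.set_params(stat_window=6000, stat_overlap=1000)
        assert clone.get_params()["stat_window"] == 6000
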