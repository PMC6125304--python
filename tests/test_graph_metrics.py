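import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (betweenness_oracle, chain_matrix,
                      min_spanning_tree_oracle, star_matrix)
from plinet.graph_metrics import (MSTFeatureExtractor, Tree, modularity,
                                  mst_kruskal, mst_mean, subject_metrics,
                                  tree_metrics, weighted_clustering,
                                  weighted_path_length)


def random_pli_matrix(n, rng):
    v = rng.uniform(0.01, 0.99, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return v


class TestKruskal:
    def test_three_node_example(self):
        m = np.array([[0.0, 0.9, 0.1],
                      [0.9, 0.0, 0.8],
                      [0.1, 0.8, 0.0]])
        tree = mst_kruskal(m)
        assert {(i, j) for i, j, _ in tree.edges} == {(0, 1), (1, 2)}

    def test_64_node_matrix_gives_valid_tree(self, rng):
        tree = mst_kruskal(random_pli_matrix(64, rng))
        assert len(tree.edges) == 63
        assert nx.is_tree(tree.graph)

    def test_chain_dominant_matrix_yields_path(self):
        tree = mst_kruskal(chain_matrix(64))
        assert {(i, j) for i, j, _ in tree.edges} == {(i, i + 1)
                                                      for i in range(63)}

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_matches_exhaustive_enumeration(self, n, rng):
        for _ in range(3):
            v = random_pli_matrix(n, rng)
            tree = mst_kruskal(v)
            best_total, best_edges = min_spanning_tree_oracle(1.0 - v)
            assert {(i, j) for i, j, _ in tree.edges} == best_edges
            total = sum(1.0 - w for _, _, w in tree.edges)
            assert total == pytest.approx(best_total)

    def test_matches_prim_total_weight(self, rng):
        v = random_pli_matrix(20, rng)
        g = nx.from_numpy_array(1.0 - v)
        prim = nx.minimum_spanning_tree(g, algorithm="prim")
        prim_total = prim.size(weight="weight")
        kruskal_total = sum(1.0 - w for _, _, w in mst_kruskal(v).edges)
        assert kruskal_total == pytest.approx(prim_total)

    def test_asymmetric_input_rejected(self):
        m = np.array([[0.0, 0.5], [0.6, 0.0]])
        with pytest.raises(ValueError):
            mst_kruskal(m)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_preserves_edge_set(self, seed):
        v = random_pli_matrix(10, np.random.default_rng(seed))
        base = {(i, j) for i, j, _ in mst_kruskal(v).edges}
        squashed = {(i, j) for i, j, _ in mst_kruskal(v ** 2).edges}
        assert base == squashed


class TestTreeMetrics:
    def test_star_closed_forms(self):
        tm = tree_metrics(mst_kruskal(star_matrix(64)))
        assert tm.leaf_raw == 63
        assert tm.diameter_raw == 2
        assert tm.bc == pytest.approx(1.0)
        assert tm.tree_hierarchy == pytest.approx(63 / (2 * 63 * 1.0))
        assert tm.kappa == pytest.approx(32.0)
        assert tm.degree_correlation == pytest.approx(-1.0)

    def test_path_closed_forms(self):
        tm = tree_metrics(mst_kruskal(chain_matrix(64)))
        assert tm.leaf_raw == 2
        assert tm.diameter_raw == 63
        assert tm.kappa == pytest.approx((4 * 64 - 6) / 126)
        assert tm.bc == pytest.approx((31 * 32) / (63 * 62 / 2))
        assert tm.tree_hierarchy == pytest.approx(
            2 / (2 * 63 * tm.bc), rel=1e-12)

    def test_two_node_tree_degenerate_metrics(self):
        tm = tree_metrics(Tree(n_nodes=2, edges=[(0, 1, 0.4)]))
        assert tm.leaf_raw == 2 and tm.diameter_raw == 1
        assert tm.kappa == pytest.approx(1.0)
        assert np.isnan(tm.degree_correlation)
        assert np.isnan(tm.tree_hierarchy)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_betweenness_matches_bruteforce_path_counting(self, seed):
        rng = np.random.default_rng(seed)
        tree = mst_kruskal(random_pli_matrix(24, rng))
        oracle = betweenness_oracle(24, [(i, j) for i, j, _ in tree.edges])
        bc = nx.betweenness_centrality(tree.graph, normalized=True)
        got = np.array([bc[i] for i in range(24)])
        np.testing.assert_allclose(got, oracle, atol=1e-12)
        assert tree_metrics(tree).bc == pytest.approx(oracle.max())

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_structural_bounds_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        tree = mst_kruskal(random_pli_matrix(n, rng))
        tm = tree_metrics(tree)
        m = n - 1
        assert 2 <= tm.leaf_raw <= n - 1
        assert tm.diameter_raw <= m - tm.leaf_raw + 2
        assert 0 <= tm.bc <= 1
        assert tm.kappa >= 1
        assert tree.degree_sequence.sum() == 2 * m

    def test_invalid_tree_rejected(self):
        with pytest.raises(ValueError):
            Tree(n_nodes=3, edges=[(0, 1, 0.5)])
        with pytest.raises(ValueError):
            Tree(n_nodes=3, edges=[(0, 1, 0.5), (0, 1, 0.5)])


class TestMstMean:
    def test_constant_weights(self):
        tree = mst_kruskal(np.full((5, 5), 0.4) - 0.4 * np.eye(5))
        assert mst_mean(tree) == pytest.approx(0.4)

    def test_chain_dominant_mean_is_strong_weight(self):
        assert mst_mean(mst_kruskal(chain_matrix(64))) == pytest.approx(0.9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_tree_mean_at_least_global_mean(self, seed):
        v = random_pli_matrix(12, np.random.default_rng(seed))
        iu = np.triu_indices(12, 1)
        assert mst_mean(mst_kruskal(v)) >= v[iu].mean()


class TestWeightedMetrics:
    def test_path_length_complete_unit_graph(self):
        assert weighted_path_length(np.ones((5, 5)) - np.eye(5)) == 1.0

    def test_path_length_two_nodes(self):
        assert weighted_path_length(np.array([[0.0, 0.5],
                                              [0.5, 0.0]])) == 2.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_path_length_matches_path_enumeration(self, seed):
        v = random_pli_matrix(6, np.random.default_rng(seed))
        g = nx.complete_graph(6)
        total = 0.0
        for s in range(6):
            for t in range(s + 1, 6):
                best = min(sum(1.0 / v[p[k], p[k + 1]]
                               for k in range(len(p) - 1))
                           for p in nx.all_simple_paths(g, s, t))
                total += best
        assert weighted_path_length(v) == pytest.approx(total / 15)

    def test_clustering_complete_graph_reduces_to_weight(self):
        for w in (1.0, 0.7, 0.2):
            m = np.full((6, 6), w) - w * np.eye(6)
            assert weighted_clustering(m) == pytest.approx(w)

    def test_clustering_star_is_zero(self):
        assert weighted_clustering(star_matrix(10, weak=0.0)) == 0.0


class TestModularity:
    def test_single_module_q_is_zero(self, rng):
        v = random_pli_matrix(6, rng)
        from plinet.graph_metrics import _modularity_value
        w = v.copy()
        assert _modularity_value(w, np.zeros(6, dtype=int)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_cliques_recovered(self):
        n = 8
        w = np.zeros((n, n))
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 1.0
        w[0, 4] = w[4, 0] = 0.1
        q, parts = modularity(w)
        assert {frozenset(p) for p in parts} == {frozenset(range(4)),
                                                 frozenset(range(4, 8))}
        assert 0.4 < q < 0.5

    def test_greedy_agrees_with_exhaustive_on_separable_graph(self):
        n = 8
        w = np.zeros((n, n))
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 1.0
        w[1, 5] = w[5, 1] = 0.05
        q_ex, _ = modularity(w, method="exhaustive")
        q_gr, _ = modularity(w, method="greedy")
        assert q_gr == pytest.approx(q_ex, abs=1e-9)

    def test_returned_q_consistent_with_partition(self, rng):
        from plinet.graph_metrics import _modularity_value
        v = random_pli_matrix(7, rng)
        q, parts = modularity(v)
        labels = np.empty(7, dtype=int)
        for lab, p in enumerate(parts):
            for node in p:
                labels[node] = lab
        w = v.copy()
        np.fill_diagonal(w, 0.0)
        assert q == pytest.approx(_modularity_value(w, labels), abs=1e-12)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            modularity(np.zeros((4, 4)))


class TestSubjectMetrics:
    def test_identical_epochs_equal_single_epoch(self, rng):
        v = random_pli_matrix(10, rng)
        single = subject_metrics([v])
        repeated = subject_metrics([v, v, v])
        for key in single:
            np.testing.assert_allclose(repeated[key], single[key])

    def test_epoch_permutation_invariance(self, rng):
        mats = [random_pli_matrix(8, rng) for _ in range(4)]
        a = subject_metrics(mats)
        b = subject_metrics(mats[::-1])
        for key in a:
            assert a[key] == pytest.approx(b[key])

    def test_epoch_averaging_shrinks_variability(self, rng):
        # metric SD across 30-epoch averages shrinks vs single epochs
        def noisy():
            return random_pli_matrix(12, rng)

        singles = [subject_metrics([noisy()], weighted=False)["kappa"]
                   for _ in range(20)]
        avgs = [np.mean([subject_metrics([noisy()], weighted=False)["kappa"]
                         for _ in range(10)]) for _ in range(10)]
        assert np.std(avgs) < np.std(singles)


def test_mst_feature_extractor_transformer(rng):
    stacks = [np.stack([random_pli_matrix(8, rng) for _ in range(2)])
              for _ in range(3)]
    est = MSTFeatureExtractor(weighted=False)
    out = est.fit_transform(stacks)
    assert out.shape[0] == 3
    assert "kappa" in out.columns and "mst_mean" in out.columns
    assert "modularity_q" not in out.columns
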