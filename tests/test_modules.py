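"""Community detection, modularity, module edge counts, participation."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from tremornet.connectivity import ConnectivityMatrix
from tremornet.modules import (
    ModularPartition,
    detect_communities,
    group_graph,
    modularity_Q,
    module_edge_counts,
    participation,
    restricted_nodal_table,
)


class TestModularityQ:
    def test_single_module_gives_zero(self):
        a = oracles.nx_to_adj(nx.gnp_random_graph(8, 0.5, seed=1))
        assert modularity_Q(a, np.zeros(8, dtype=int)) == pytest.approx(0.0)

    def test_two_disjoint_cliques_split_gives_half(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        labels = np.array([0] * 4 + [1] * 4)
        assert modularity_Q(oracles.nx_to_adj(g), labels) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_definitional_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(12, 0.4, seed=seed)
        a = oracles.nx_to_adj(g)
        labels = rng.integers(0, 3, size=12)
        assert modularity_Q(a, labels) == pytest.approx(
            oracles.modularity_oracle(a, labels), abs=1e-12
        )


class TestDetectCommunities:
    def test_two_disjoint_cliques_recovered(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        part = detect_communities(oracles.nx_to_adj(g))
        assert part.n_modules == 2
        assert len(set(part.assignment[:4])) == 1
        assert len(set(part.assignment[4:])) == 1
        assert part.Q == pytest.approx(0.5)
        assert part.nonrandom

    def test_bridged_cliques_match_exhaustive_search(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        a = oracles.nx_to_adj(g)
        part = detect_communities(a)
        best_q, best_blocks = oracles.best_partition_oracle(a)
        assert part.Q == pytest.approx(best_q)
        assert part.n_modules == 2
        assert len(set(part.assignment[:5])) == 1 and len(set(part.assignment[5:])) == 1

    def test_greedy_never_beats_exhaustive_optimum(self):
        for g in oracles.random_graphs(6, 7, seed=21):
            a = oracles.nx_to_adj(g)
            if a.sum() == 0:
                continue
            best_q, _ = oracles.best_partition_oracle(a)
            assert detect_communities(a).Q <= best_q + 1e-12

    def test_edgeless_graph_gives_singletons(self):
        part = detect_communities(np.zeros((5, 5), dtype=bool))
        assert part.n_modules == 5
        assert part.Q == 0.0

    def test_planted_block_model_recovered_with_high_nmi(self):
        from sklearn.metrics import normalized_mutual_info_score

        sizes = [15] * 6
        g = nx.stochastic_block_model(
            sizes, np.full((6, 6), 0.03) + np.eye(6) * 0.57, seed=4
        )
        part = detect_communities(oracles.nx_to_adj(g))
        planted = np.repeat(np.arange(6), 15)
        assert normalized_mutual_info_score(planted, part.assignment) >= 0.9


class TestGroupGraph:
    def test_single_subject_group_graph_is_own_slice(self, rng):
        n = 20
        w = np.abs(rng.normal(size=(n, n)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        fc = ConnectivityMatrix(w, "s", "baseline")
        adj_one, _ = group_graph([fc], 0.15)
        adj_two, _ = group_graph([fc, fc], 0.15)  # idempotent mean
        np.testing.assert_array_equal(adj_one, adj_two)
        # 0.15 * 190 = 28.5 ties; the documented rule rounds half-up
        assert adj_one.sum() // 2 == int(0.15 * n * (n - 1) / 2 + 0.5)

    def test_study_scale_edge_count(self, rng):
        n = 273
        w = np.abs(rng.normal(size=(n, n))) + 0.01
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        adj, _ = group_graph([ConnectivityMatrix(w, "s", "baseline")], 0.15)
        assert adj.sum() // 2 == 5569


class TestModuleEdgeCounts:
    def test_complete_graph_block_counts(self):
        a = oracles.nx_to_adj(nx.complete_graph(5))
        part = ModularPartition(np.array([0, 0, 1, 1, 1]), 0.0)
        counts = module_edge_counts(a, part).counts
        assert counts[0, 0] == 1 and counts[1, 1] == 3
        assert counts[0, 1] == counts[1, 0] == 6

    def test_empty_graph_all_zero(self):
        part = ModularPartition(np.array([0, 1, 0, 1]), 0.0)
        counts = module_edge_counts(np.zeros((4, 4), dtype=bool), part).counts
        assert counts.sum() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_edge_tally_oracle_and_conserves_total(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(20, 0.3, seed=seed)
        a = oracles.nx_to_adj(g)
        labels = rng.integers(0, 3, size=20)
        part = ModularPartition(labels, 0.0)
        counts = module_edge_counts(a, part)
        np.testing.assert_array_equal(counts.counts, oracles.module_counts_oracle(a, labels))
        assert counts.total_edges == g.number_of_edges()

    def test_size_mismatch_rejected(self):
        part = ModularPartition(np.array([0, 1]), 0.0)
        with pytest.raises(ValueError):
            module_edge_counts(np.zeros((3, 3), dtype=bool), part)


class TestParticipation:
    def test_all_edges_in_own_module_scores_zero(self):
        a = oracles.nx_to_adj(nx.complete_graph(4))
        full = np.zeros((6, 6), dtype=bool)
        full[:4, :4] = a
        part = ModularPartition(np.array([0, 0, 0, 0, 1, 1]), 0.0)
        p = participation(full, part)
        np.testing.assert_allclose(p[:4], 0.0)
        np.testing.assert_allclose(p[4:], 0.0)  # isolated nodes also 0

    def test_evenly_split_degree_four_node(self):
        a = np.zeros((5, 5), dtype=bool)
        for j in (1, 2, 3, 4):
            a[0, j] = a[j, 0] = True
        part = ModularPartition(np.array([0, 1, 1, 2, 2]), 0.0)
        assert participation(a, part)[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_definitional_oracle_and_bound(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(15, 0.4, seed=seed)
        a = oracles.nx_to_adj(g)
        labels = rng.integers(0, 4, size=15)
        part = ModularPartition(labels, 0.0)
        p = participation(a, part)
        np.testing.assert_allclose(p, oracles.participation_oracle(a, labels), atol=1e-12)
        assert p.max() <= 1 - 1 / 4 + 1e-12

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_under_module_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        a = rng.random((n, n)) < 0.4
        a = np.triu(a, 1)
        a = a | a.T
        labels = rng.integers(0, 3, size=n)
        perm = rng.permutation(3)
        p1 = participation(a, ModularPartition(labels, 0.0))
        p2 = participation(a, ModularPartition(perm[labels], 0.0))
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestRestrictedTable:
    def _tables(self):
        import pandas as pd

        nodal = pd.DataFrame(
            {
                "subject": ["s1"] * 6,
                "session": ["baseline"] * 6,
                "node": [0, 1, 2, 3, 4, 5],
                "metric": ["betweenness"] * 6,
                "value": np.arange(6.0),
            }
        )
        part_tab = nodal.assign(metric="participation")
        return nodal, part_tab

    def test_restricts_to_implicated_module_nodes(self):
        nodal, part_tab = self._tables()
        part = ModularPartition(np.array([0, 0, 1, 1, 2, 2]), 0.4)
        out = restricted_nodal_table(nodal, part_tab, part, {0, 2})
        assert set(out["node"]) == {0, 1, 4, 5}
        assert set(out["metric"]) == {"betweenness", "participation"}

    def test_no_implicated_modules_gives_empty_table(self):
        nodal, part_tab = self._tables()
        part = ModularPartition(np.array([0, 0, 1, 1, 2, 2]), 0.4)
        out = restricted_nodal_table(nodal, part_tab, part, set())
        assert out.empty
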