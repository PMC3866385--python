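"""Modularity, Qcut-style parcellation, junk-module analyses."""

import itertools

import numpy as np
import pytest

import gsrnet as g
from gsrnet.modules import JUNK_ID, Partition


def oracle_modularity(adj, labels):
    """O(n^2) double-loop Newman Q."""
    m = adj.sum() / 2
    deg = adj.sum(axis=1)
    q = 0.0
    for i in range(len(adj)):
        for j in range(len(adj)):
            if labels[i] == labels[j]:
                q += adj[i, j] - deg[i] * deg[j] / (2 * m)
    return q / (2 * m)


def exhaustive_best_partition(adj):
    """Enumerate every partition (set-partition) of the node set."""
    n = len(adj)

    def partitions(nodes):
        if not nodes:
            yield []
            return
        first, rest = nodes[0], nodes[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    best_q, best = -np.inf, None
    for part in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, grp in enumerate(part):
            labels[grp] = c
        q = oracle_modularity(adj, labels)
        if q > best_q:
            best_q, best = q, labels
    return best_q, best


def random_graph(rng, n, p):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T


class TestModularityQ:
    def test_single_module_zero(self, clique_bridge_network):
        labels = np.zeros(8, dtype=int)
        assert g.modularity_Q(clique_bridge_network, labels) == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_clique_hand_value(self, clique_bridge_network):
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert g.modularity_Q(clique_bridge_network, labels) == \
            pytest.approx(12 / 13 - 0.5, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_partitions_match_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        adj = random_graph(rng, n, 0.3)
        if adj.sum() == 0:
            return
        labels = rng.integers(0, 4, size=n)
        net = g.network_from_adjacency(adj)
        assert g.modularity_Q(net, labels) == pytest.approx(
            oracle_modularity(adj, labels), abs=1e-12)


class TestQcutPartition:
    def test_two_cliques_recovers_optimum(self, clique_bridge_network):
        part = g.qcut_partition(clique_bridge_network)
        assert part.Q == pytest.approx(12 / 13 - 0.5, abs=1e-9)
        assert part.n_modules == 2
        # exhaustive search over all 4140 partitions confirms optimality
        best_q, _ = exhaustive_best_partition(
            clique_bridge_network.adjacency.toarray())
        assert part.Q == pytest.approx(best_q, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_small_graph_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 8
        adj = random_graph(rng, n, 0.35)
        net = g.network_from_adjacency(adj)
        comp = g.components(net)
        if comp.giant_size < 2:
            return
        part = g.qcut_partition(net)
        giant = comp.giant_mask()
        sub = adj[np.ix_(giant, giant)]
        best_q, _ = exhaustive_best_partition(sub)
        assert part.Q >= best_q - 1e-9 or part.Q == pytest.approx(best_q,
                                                                  abs=1e-9)

    def test_no_structure_single_module(self):
        k10 = g.network_from_adjacency(np.ones((10, 10)) - np.eye(10))
        part = g.qcut_partition(k10)
        assert part.n_modules == 1
        assert part.Q == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_planted_partition_recovery(self, seed):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(seed)
        blocks = np.repeat(np.arange(4), 25)
        p = np.where(blocks[:, None] == blocks[None, :], 0.5, 0.02)
        adj = np.triu(rng.random((100, 100)) < p, 1)
        net = g.network_from_adjacency(adj + adj.T)
        part = g.qcut_partition(net, seed=seed)
        giant = ~part.junk_mask
        ari = adjusted_rand_score(blocks[giant], part.labels[giant])
        assert ari >= 0.9

    def test_junk_collects_everything_outside_giant(self):
        a = np.zeros((12, 12))
        for blk in (range(5), range(5, 9)):  # 5-clique and 4-clique
            for i in blk:
                for j in blk:
                    if i != j:
                        a[i, j] = 1
        # nodes 9, 10, 11 isolated
        part = g.qcut_partition(g.network_from_adjacency(a))
        assert part.junk_size == 7  # the 4-clique + 3 isolates
        assert set(np.flatnonzero(part.junk_mask)) == {5, 6, 7, 8, 9, 10, 11}

    def test_beats_random_partitions(self):
        rng = np.random.default_rng(11)
        blocks = np.repeat(np.arange(3), 15)
        p = np.where(blocks[:, None] == blocks[None, :], 0.5, 0.05)
        adj = np.triu(rng.random((45, 45)) < p, 1)
        net = g.network_from_adjacency(adj + adj.T)
        part = g.qcut_partition(net)
        assert part.Q >= 0.0
        comp = g.components(net)
        giant = comp.giant_mask()
        sub = g.network_from_adjacency(adj[np.ix_(giant, giant)]
                                       + adj.T[np.ix_(giant, giant)])
        for _ in range(20):
            rnd = rng.integers(0, part.n_modules, size=int(giant.sum()))
            assert part.Q >= g.modularity_Q(sub, rnd) - 1e-12

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        adj = random_graph(rng, 60, 0.1)
        net = g.network_from_adjacency(adj)
        p1 = g.qcut_partition(net, seed=3)
        p2 = g.qcut_partition(net, seed=3)
        assert np.array_equal(p1.labels, p2.labels)
        assert p1.Q == p2.Q


class TestJunkWmCount:
    def _partition(self, labels):
        arr = np.asarray(labels)
        n_mod = len([c for c in np.unique(arr) if c != JUNK_ID])
        return Partition(labels=arr, junk_id=JUNK_ID, Q=0.1,
                         n_modules=n_mod)

    def test_empty_junk(self):
        part = self._partition([0, 0, 1, 1])
        rep = g.junk_wm_count(part, np.array([True, True, False, False]))
        assert rep.n_junk_wm_adjacent == 0 and rep.n_junk == 0

    def test_all_junk_adjacent(self):
        part = self._partition([JUNK_ID, JUNK_ID, 0, 0])
        rep = g.junk_wm_count(part, np.array([True, True, True, False]))
        assert rep.n_junk_wm_adjacent == 2 and rep.n_junk == 2

    def test_accepts_phantom_labels(self, small_phantom):
        labels = np.zeros(small_phantom.n_nodes, dtype=int)
        labels[:10] = JUNK_ID
        part = self._partition(labels)
        rep = g.junk_wm_count(part, small_phantom)
        expect = int(small_phantom.wm_adjacent[:10].sum())
        assert rep.n_junk_wm_adjacent == expect


class TestModuleOverlap:
    def _partition(self, labels):
        arr = np.asarray(labels)
        n_mod = len([c for c in np.unique(arr) if c != JUNK_ID])
        return Partition(labels=arr, junk_id=JUNK_ID, Q=0.1,
                         n_modules=n_mod)

    def test_identical_partitions(self):
        part = self._partition([0, 0, 1, 1, JUNK_ID])
        om = g.module_overlap([part] * 5, np.array([2]))
        assert om.counts.tolist() == [0, 0, 5, 5, 0]

    def test_tie_breaks_to_lower_module_id(self):
        part = self._partition([0, 0, 1, 1])
        om = g.module_overlap([part], np.array([0, 2]))  # straddles equally
        assert om.counts.tolist() == [1, 1, 0, 0]

    def test_empty_seed_errors(self):
        part = self._partition([0, 1])
        with pytest.raises(ValueError):
            g.module_overlap([part], np.array([], dtype=int))


class TestExcludeWmAdjacentRerun:
    def test_no_adjacent_nodes_identical(self):
        rng = np.random.default_rng(13)
        cm = g.correlation_matrix(rng.standard_normal((30, 40)))
        l_with, l_without = g.exclude_wm_adjacent_rerun(
            cm, np.zeros(30, dtype=bool), 2.0)
        assert l_with == l_without

    def test_returns_both_lengths(self, shared_signal_dataset, small_phantom):
        cm = g.correlation_matrix(shared_signal_dataset)
        l_with, l_without = g.exclude_wm_adjacent_rerun(
            cm, small_phantom.wm_adjacent, 3.0)
        assert l_with >= 1.0 and l_without >= 1.0
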