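"""Subcluster construction, connection graph, greedy supercluster phasing."""

from itertools import product

import numpy as np
import pytest

from ibdphase import (ClusterConfig, build_connection_graph, build_subclusters,
                      phase_superclusters, prune_supercluster,
                      score_orientation)
from ibdphase.cluster import ConnectionEdge, ConnectionGraph, Supercluster
from ibdphase.ibd import IBDSegment
from ibdphase.split import Fragment, GroupAssignment


def _assignment(fragments, votes_per_seg):
    """GroupAssignment with unit-weight votes at the given site lists."""
    a = GroupAssignment()
    a.fragments = fragments
    for seg_id, sites in votes_per_seg.items():
        sites = np.asarray(sites)
        a.seg_votes[seg_id] = (sites, np.zeros(len(sites), np.int8),
                               np.ones(len(sites)))
    return a


def _frag(fid, seg_id, other, chrom, start, end, side=0, cm=10.0):
    return Fragment(fid, seg_id, other, chrom, start, end, side, cm)


class TestSubclusters:
    @pytest.mark.parametrize("n_common,expect_clusters", [(12, 1), (8, 2)])
    def test_minimum_weighted_overlap(self, n_common, expect_clusters):
        """>= 10.0 weighted shared informative sites joins two fragments
        into one subcluster; fewer keeps them apart."""
        f1 = _frag(0, 0, "u", "1", 0, 30)
        f2 = _frag(1, 1, "v", "1", 10, 40)
        common = list(range(10, 10 + n_common))
        a = _assignment([f1, f2], {0: list(range(0, 10)) + common,
                                   1: common + list(range(35, 40))})
        subs = build_subclusters(a)
        assert len(subs) == expect_clusters

    def test_zero_segments_zero_subclusters(self):
        assert build_subclusters(_assignment([], {})) == []


class TestConnectionGraph:
    def _setup(self, frags, seg_cm):
        a = _assignment(frags, {f.seg_id: [] for f in frags})
        subs = build_subclusters(a, ClusterConfig(min_weighted_overlap=1e9))
        segments = [IBDSegment(o, "1", 0, 1, cm, cm) for o, cm in seg_cm]
        return subs, build_connection_graph(subs, a, segments)

    def test_multi_subcluster_individual_makes_one_weighted_edge(self):
        """An individual with fragments in two subclusters (30 cM total
        shared) contributes one edge of weight 30."""
        frags = [_frag(0, 0, "C", "1", 0, 10), _frag(1, 1, "C", "2", 0, 10)]
        _subs, graph = self._setup(frags, [("C", 18.0), ("C", 12.0)])
        assert len(graph.edges) == 1
        e = next(iter(graph.edges.values()))
        assert e.w_same == pytest.approx(30.0)
        assert e.n_connections == 1

    def test_single_subcluster_individuals_give_edgeless_graph(self):
        frags = [_frag(0, 0, "u", "1", 0, 10), _frag(1, 1, "v", "2", 0, 10)]
        _subs, graph = self._setup(frags, [("u", 10.0), ("v", 10.0)])
        assert graph.edges == {}

    def test_three_subclusters_make_three_pairwise_edges(self):
        frags = [_frag(i, i, "C", str(i + 1), 0, 10) for i in range(3)]
        _subs, graph = self._setup(frags, [("C", 10.0)] * 3)
        assert len(graph.edges) == 3


def _graph(n, edge_spec):
    """edge_spec: (a, b, w_same, w_diff, n_same, n_diff)."""
    g = ConnectionGraph(n_nodes=n)
    for a, b, ws, wd, ns, nd in edge_spec:
        g.edges[(a, b)] = ConnectionEdge(a, b, ws, wd, ns, nd)
    return g


def _exhaustive_best(graph):
    n = graph.n_nodes
    return max(score_orientation(graph, dict(enumerate(bits)))
               for bits in product((0, 1), repeat=n))


class TestScoring:
    def test_single_edge_satisfied_or_violated(self):
        g = _graph(2, [(0, 1, 5.0, 0.0, 1, 0)])
        assert score_orientation(g, {0: 0, 1: 0}) == 5.0
        assert score_orientation(g, {0: 0, 1: 1}) == 0.0

    def test_global_flip_symmetry(self):
        rng = np.random.default_rng(0)
        g = _graph(5, [(a, b, rng.uniform(0, 5), rng.uniform(0, 5), 1, 0)
                       for a in range(5) for b in range(a + 1, 5)])
        bits = {i: int(b) for i, b in enumerate(rng.integers(0, 2, 5))}
        flipped = {i: 1 - b for i, b in bits.items()}
        assert score_orientation(g, bits) == pytest.approx(
            score_orientation(g, flipped))

    def test_single_flip_identity(self):
        """Flipping one node changes the score by exactly the swing of its
        incident edges (checked against direct re-scoring)."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            g = _graph(6, [(a, b, rng.uniform(0, 5), rng.uniform(0, 5), 1, 0)
                           for a in range(6) for b in range(a + 1, 6)
                           if rng.random() < 0.6])
            bits = {i: int(x) for i, x in enumerate(rng.integers(0, 2, 6))}
            node = int(rng.integers(0, 6))
            before = score_orientation(g, bits)
            swing = 0.0
            for e in g.edges.values():
                if node in (e.a, e.b):
                    other = e.b if e.a == node else e.a
                    cur = e.w_same if bits[node] == bits[other] else e.w_diff
                    new = e.w_diff if bits[node] == bits[other] else e.w_same
                    swing += new - cur
            bits[node] ^= 1
            assert score_orientation(g, bits) == pytest.approx(before + swing)


class TestGreedyPhasing:
    def test_consistent_component_reaches_total_weight(self):
        g = _graph(3, [(0, 1, 4.0, 0.0, 1, 0), (1, 2, 3.0, 0.0, 1, 0),
                       (0, 2, 2.0, 0.0, 1, 0)])
        sup = phase_superclusters(g, [], ClusterConfig(restarts=20), seed=0)
        assert len(sup) == 1
        assert sup[0].score == pytest.approx(9.0)
        bits = sup[0].orientation
        assert len(set(bits.values())) == 1  # all aligned (up to global flip)

    def test_edgeless_graph_gives_singletons(self):
        g = _graph(4, [])
        sup = phase_superclusters(g, [], ClusterConfig(restarts=5), seed=0)
        assert [s.members for s in sup] == [[0], [1], [2], [3]]

    def test_greedy_matches_exhaustive_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            spec = [(a, b, rng.uniform(0, 10) * (rng.random() < 0.5),
                     rng.uniform(0, 10) * (rng.random() < 0.5), 1, 0)
                    for a in range(8) for b in range(a + 1, 8)
                    if rng.random() < 0.4]
            g = _graph(8, spec)
            sup = phase_superclusters(g, [], ClusterConfig(restarts=200), seed=1)
            assert sum(s.score for s in sup) == pytest.approx(_exhaustive_best(g))

    def test_restart_scores_reproducible(self):
        g = _graph(4, [(0, 1, 1.0, 2.0, 1, 0), (1, 2, 3.0, 1.0, 1, 0),
                       (2, 3, 2.0, 2.5, 1, 0)])
        s1 = phase_superclusters(g, [], ClusterConfig(restarts=50), seed=7)
        s2 = phase_superclusters(g, [], ClusterConfig(restarts=50), seed=7)
        assert [s.orientation for s in s1] == [s.orientation for s in s2]


class TestPruning:
    def test_connection_count_threshold(self):
        """2 connections to the rest -> removed; 3 -> retained."""
        for n_con, kept in [(2, 1), (3, 2)]:
            g = _graph(2, [(0, 1, 1.0, 0.0, n_con, 0)])
            sup = Supercluster(0, [0, 1], {0: 0, 1: 0}, 0.0)
            pruned = prune_supercluster(sup, g)
            assert len(pruned.pruned_members) == kept \
                if n_con == 3 else len(pruned.pruned_members) == 0

    def test_chain_cascades_to_empty(self):
        g = _graph(3, [(0, 1, 1.0, 0.0, 1, 0), (1, 2, 1.0, 0.0, 1, 0)])
        sup = Supercluster(0, [0, 1, 2], {0: 0, 1: 0, 2: 0}, 0.0)
        assert prune_supercluster(sup, g).pruned_members == []
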