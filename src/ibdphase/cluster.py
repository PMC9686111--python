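"""Subclusters, connection graph, and supercluster phasing.

A *subcluster* is a connected block of sided IBD fragments on one
chromosome, where two fragments are linked when they overlap on enough
weighted informative sites (proband heterozygous, both fragments
homozygous) to trust their relative side assignment.

Subclusters in different genomic regions are aligned into *superclusters*
through database individuals that share IBD with the proband in more than
one subcluster: both shared haplotypes most likely come from the same
parent.  Choosing the per-subcluster orientation (local side 0 -> global
side A or B) that maximises the total weight of such satisfied
connections is a weighted graph-bipartition problem, solved by greedy
single-flip local search from many random starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .ibd import IBDSegment
from .split import Fragment, GroupAssignment


@dataclass
class ClusterConfig:
    min_weighted_overlap: float = 10.0  # weighted informative sites linking two fragments
    restarts: int = 1000                # random restarts of the greedy optimizer
    min_connections: int = 3            # supercluster pruning threshold


@dataclass
class Subcluster:
    id: int
    chrom: str
    members: list[tuple[int, int]]      # (fragment id, local side)
    span: tuple[int, int]               # site-index interval (half open)


@dataclass
class ConnectionEdge:
    """Aggregated connections between two subclusters.

    ``w_same``/``n_same`` hold the weight/count of individuals whose
    fragments sit on local sides that should map to the same parent when
    the two subclusters' orientations are equal; ``w_diff``/``n_diff``
    when they should differ.
    """

    a: int
    b: int
    w_same: float = 0.0
    w_diff: float = 0.0
    n_same: int = 0
    n_diff: int = 0

    @property
    def n_connections(self) -> int:
        return self.n_same + self.n_diff


@dataclass
class ConnectionGraph:
    n_nodes: int
    edges: dict[tuple[int, int], ConnectionEdge] = field(default_factory=dict)

    def incident(self) -> dict[int, list[ConnectionEdge]]:
        out: dict[int, list[ConnectionEdge]] = {i: [] for i in range(self.n_nodes)}
        for e in self.edges.values():
            out[e.a].append(e)
            out[e.b].append(e)
        return out

    def components(self) -> list[list[int]]:
        parent = list(range(self.n_nodes))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (a, b) in self.edges:
            parent[find(a)] = find(b)
        comp: dict[int, list[int]] = {}
        for i in range(self.n_nodes):
            comp.setdefault(find(i), []).append(i)
        return sorted(comp.values(), key=lambda c: c[0])


@dataclass
class Supercluster:
    id: int
    members: list[int]                  # subcluster ids
    orientation: dict[int, int]         # subcluster id -> bit (local 0 -> A if 0)
    score: float
    pruned_members: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------

def _fragment_votes(frag: Fragment, assignment: GroupAssignment):
    idx, allele, wts = assignment.seg_votes[frag.seg_id]
    m = (idx >= frag.start) & (idx < frag.end)
    return idx[m], wts[m]


def weighted_overlap(f1: Fragment, f2: Fragment, assignment: GroupAssignment) -> float:
    """Weighted count of sites heterozygous in the proband and homozygous
    in both fragments (each site weighted by the product of the two
    fragments' endpoint weights)."""
    if f1.chrom != f2.chrom or f1.start >= f2.end or f2.start >= f1.end:
        return 0.0
    i1, w1 = _fragment_votes(f1, assignment)
    i2, w2 = _fragment_votes(f2, assignment)
    common, a_idx, b_idx = np.intersect1d(i1, i2, return_indices=True)
    if not len(common):
        return 0.0
    return float(np.dot(w1[a_idx], w2[b_idx]))


def build_subclusters(assignment: GroupAssignment,
                      cfg: ClusterConfig = ClusterConfig()) -> list[Subcluster]:
    """Connected components of fragments under the weighted-overlap relation."""
    frags = assignment.fragments
    by_chrom: dict[str, list[Fragment]] = {}
    for f in frags:
        by_chrom.setdefault(f.chrom, []).append(f)
    out: list[Subcluster] = []
    next_id = 0
    for chrom, fl in by_chrom.items():
        fl = sorted(fl, key=lambda f: f.start)
        parent = list(range(len(fl)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(fl)):
            for j in range(i + 1, len(fl)):
                if fl[j].start >= fl[i].end:
                    break
                if find(i) == find(j):
                    continue
                if weighted_overlap(fl[i], fl[j], assignment) >= cfg.min_weighted_overlap:
                    parent[find(i)] = find(j)
        groups: dict[int, list[Fragment]] = {}
        for i, f in enumerate(fl):
            groups.setdefault(find(i), []).append(f)
        for g in sorted(groups.values(), key=lambda g: g[0].start):
            out.append(Subcluster(
                id=next_id, chrom=chrom,
                members=[(f.id, f.side) for f in g],
                span=(min(f.start for f in g), max(f.end for f in g))))
            next_id += 1
    return out


def build_connection_graph(subclusters: list[Subcluster],
                           assignment: GroupAssignment,
                           segments: list[IBDSegment]) -> ConnectionGraph:
    """One edge contribution per (individual, subcluster pair).

    An individual with fragments in several subclusters connects every
    pair of them; the connection weight is the individual's total
    proband-shared cM, and its parity records whether the fragments'
    local sides should align under equal orientations.
    """
    frag_by_id = {f.id: f for f in assignment.fragments}
    total_cm: dict[str, float] = {}
    for s in segments:
        total_cm[s.other_id] = total_cm.get(s.other_id, 0.0) + s.cm_length
    # individual -> subcluster -> cM-dominant local side
    indiv_sc: dict[str, dict[int, dict[int, float]]] = {}
    for sc in subclusters:
        for fid, side in sc.members:
            f = frag_by_id[fid]
            d = indiv_sc.setdefault(f.other_id, {}).setdefault(sc.id, {0: 0.0, 1: 0.0})
            d[side] += f.cm
    graph = ConnectionGraph(n_nodes=len(subclusters))
    for ind, per_sc in indiv_sc.items():
        if len(per_sc) < 2:
            continue
        dom = {sc_id: (0 if w[0] >= w[1] else 1) for sc_id, w in per_sc.items()}
        w = total_cm.get(ind, 0.0)
        for i, j in combinations(sorted(per_sc), 2):
            key = (i, j)
            e = graph.edges.setdefault(key, ConnectionEdge(i, j))
            if dom[i] == dom[j]:
                e.w_same += w
                e.n_same += 1
            else:
                e.w_diff += w
                e.n_diff += 1
    return graph


def score_orientation(graph: ConnectionGraph, orientation: dict[int, int]) -> float:
    """Total weight of connections satisfied by the orientation bits."""
    score = 0.0
    for e in graph.edges.values():
        if e.a in orientation and e.b in orientation:
            score += e.w_same if orientation[e.a] == orientation[e.b] else e.w_diff
    return score


def _greedy(nodes: list[int], incident, bits: dict[int, int]) -> None:
    """Single-flip hill climbing: repeatedly flip the node with the largest
    positive score gain (ties -> lowest id) until no flip gains."""
    order = sorted(nodes)  # ascending scan + strict improvement = lowest-id ties
    while True:
        best_gain, best_node = 1e-12, None
        for n in order:
            gain = 0.0
            for e in incident[n]:
                other = e.b if e.a == n else e.a
                cur = e.w_same if bits[n] == bits[other] else e.w_diff
                new = e.w_diff if bits[n] == bits[other] else e.w_same
                gain += new - cur
            if gain > best_gain:
                best_gain, best_node = gain, n
        if best_node is None:
            return
        bits[best_node] ^= 1


def phase_superclusters(graph: ConnectionGraph, subclusters: list[Subcluster],
                        cfg: ClusterConfig = ClusterConfig(),
                        seed: int = 0) -> list[Supercluster]:
    """Orient every connected component by greedy search with random restarts.

    Restart ``r`` of component ``c`` draws its initial orientation from an
    independent seeded substream, so results are reproducible and
    independent of evaluation order.
    """
    incident = graph.incident()
    out: list[Supercluster] = []
    for ci, comp in enumerate(graph.components()):
        if len(comp) == 1 or not any(incident[n] for n in comp):
            out.append(Supercluster(ci, comp, {n: 0 for n in comp}, 0.0))
            continue
        best_bits, best_score = None, -np.inf
        for r in range(cfg.restarts):
            rng = np.random.default_rng(np.random.SeedSequence([seed, ci, r]))
            bits = {n: int(b) for n, b in zip(comp, rng.integers(0, 2, len(comp)))}
            _greedy(comp, incident, bits)
            sc = _component_score(graph, comp, bits)
            if sc > best_score:
                best_score, best_bits = sc, dict(bits)
        out.append(Supercluster(ci, comp, best_bits, float(best_score)))
    return out


def _component_score(graph: ConnectionGraph, comp: list[int],
                     bits: dict[int, int]) -> float:
    score = 0.0
    comp_set = set(comp)
    for e in graph.edges.values():
        if e.a in comp_set and e.b in comp_set:
            score += e.w_same if bits[e.a] == bits[e.b] else e.w_diff
    return score


def prune_supercluster(sc: Supercluster, graph: ConnectionGraph,
                       min_connections: int = 3) -> Supercluster:
    """Iteratively drop members with fewer than ``min_connections``
    connections to the remaining members.  Pruning restricts the
    high-confidence labeling; it does not alter the genome-wide phase."""
    members = set(sc.members)
    changed = True
    while changed and members:
        changed = False
        for n in sorted(members):
            ncon = 0
            for e in graph.edges.values():
                if e.a == n and e.b in members:
                    ncon += e.n_connections
                elif e.b == n and e.a in members:
                    ncon += e.n_connections
            if ncon < min_connections:
                members.discard(n)
                changed = True
                break
    pruned = sorted(members)
    return Supercluster(sc.id, sc.members, sc.orientation, sc.score, pruned)


# ---------------------------------------------------------------------------

def fragment_global_sides(subclusters: list[Subcluster],
                          superclusters: list[Supercluster]) -> dict[int, int]:
    """Global side (A=0/B=1) per fragment: local side XOR subcluster bit."""
    orient: dict[int, int] = {}
    for sup in superclusters:
        orient.update(sup.orientation)
    sides: dict[int, int] = {}
    for sc in subclusters:
        bit = orient.get(sc.id, 0)
        for fid, side in sc.members:
            sides[fid] = side ^ bit
    return sides


def largest_supercluster(superclusters: list[Supercluster],
                         subclusters: list[Subcluster]) -> Supercluster | None:
    """The supercluster holding the most fragments (ties -> lowest id)."""
    if not superclusters:
        return None
    size = {sc.id: len(sc.members) for sc in subclusters}
    return max(superclusters, key=lambda s: (sum(size.get(m, 0) for m in s.members), -s.id))
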