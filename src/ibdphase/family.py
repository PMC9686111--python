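"""Close-family screening.

Individuals sharing a large amount of IBD with the proband (>= 400 cM by
default) are "close family".  Some of them are useless or harmful for
phasing: identical twins and full siblings share DNA on both sides of the
family, and so do descendants of both of the proband's parents (a nephew,
a grandchild).  Twins and siblings are recognised by their IBD2 pattern;
descendants of both parents are recognised structurally — they share IBD
with *every* other close relative, whereas a one-sided relative (an aunt,
a grandparent) only shares with the close family on its own side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .ibd import DetectConfig, GenotypeMatrix, IBDSegment, RelationshipStats, detect_ibd_segments

IDENTICAL_TWIN = "identical_twin"
FULL_SIBLING = "full_sibling"
OTHER = "other"

#: minimum total shared cM to count as close family
CLOSE_FAMILY_CM = 400.0
#: IBD2-run genome fraction above which a pair is an identical twin
TWIN_IBD2_FRACTION = 0.90
#: full-sibling rule: total sharing, IBD2-run fraction, and IBD1-rate cap
SIBLING_TOTAL_CM = 1300.0
SIBLING_IBD2_FRACTION = 0.09
SIBLING_IBD1_CAP = 0.99


@dataclass
class CloseFamilyGraph:
    """Close relatives and the IBD-sharing edges among them."""

    graph: nx.Graph
    flags: dict[str, set] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def missing_edges(self) -> int:
        """Pairs of close family that do not share IBD with each other."""
        n = self.graph.number_of_nodes()
        return n * (n - 1) // 2 - self.graph.number_of_edges()


def select_close_relatives(stats: dict[str, RelationshipStats],
                           threshold_cm: float = CLOSE_FAMILY_CM) -> set[str]:
    """Individuals whose total detected sharing reaches ``threshold_cm``."""
    return {k for k, s in stats.items() if s.total_shared_cm >= threshold_cm}


def classify_relationship(s: RelationshipStats) -> str:
    """Identical twin / full sibling / other, from genome-wide IBD patterns."""
    if s.ibd2_run_fraction >= TWIN_IBD2_FRACTION:
        return IDENTICAL_TWIN
    if (s.total_shared_cm >= SIBLING_TOTAL_CM
            and s.ibd2_run_fraction >= SIBLING_IBD2_FRACTION
            and s.ibd1_rate < SIBLING_IBD1_CAP):
        return FULL_SIBLING
    return OTHER


def build_family_graph(close: set[str], g: GenotypeMatrix,
                       stats: dict[str, RelationshipStats],
                       cfg: DetectConfig = DetectConfig()) -> CloseFamilyGraph:
    """Edges join close relatives that share >= 1 detected segment with
    each other (the proband is not a node)."""
    G: nx.Graph = nx.Graph()
    G.add_nodes_from(close)
    members = sorted(close)
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            if detect_ibd_segments(a, b, g, cfg):
                G.add_edge(a, b)
    fg = CloseFamilyGraph(G)
    for m in members:
        fg.flags[m] = set()
        kind = classify_relationship(stats[m])
        if kind != OTHER:
            fg.flags[m].add(kind)
    return fg


def discard_unreliable(fg: CloseFamilyGraph,
                       segments: list[IBDSegment]
                       ) -> tuple[list[IBDSegment], set[str]]:
    """Drop segments from twins, full siblings, and suspected descendants
    of both parents.

    The descendant test — adjacency to every other close relative — is
    only applied when there are at least two *other* close relatives;
    with fewer the test is vacuous and the relative is kept.
    """
    discarded: set[str] = set()
    nodes = fg.nodes
    for m in nodes:
        if IDENTICAL_TWIN in fg.flags[m] or FULL_SIBLING in fg.flags[m]:
            discarded.add(m)
    for m in nodes:
        others = [n for n in nodes if n != m]
        if len(others) >= 2 and all(fg.graph.has_edge(m, n) for n in others):
            fg.flags[m].add("descendant_candidate")
            discarded.add(m)
    kept = [s for s in segments if s.other_id not in discarded]
    return kept, discarded
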