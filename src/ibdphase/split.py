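"""Separation of IBD segments into two parental groups.

At a site where the proband is heterozygous, an overlapping IBD segment
whose database individual is homozygous tells us which of the proband's
two alleles lies on the shared haplotype.  Scanning the proband's
heterozygous sites left to right, each site partitions the overlapping
homozygous segments into two camps (one per allele); the scan keeps the
partition maximally consistent with the sides segments were assigned at
the previous heterozygous site.  Segments that are nevertheless forced to
switch sides are broken at that point.

Two robustness devices from the method:

* **Endpoint down-weighting** — detected IBD endpoints overshoot the true
  shared haplotype, so a segment's votes are weighted by a sigmoid of the
  cM distance to its nearer end.
* **Lookahead** — a genotyping error that miscalls a homozygous proband
  site as heterozygous would force many segments onto one side and corrupt
  the groups downstream.  When a site would force >= 1.0 weighted segments
  to switch, the 20 heterozygous sites on each flank are polled; if the
  flanks contradict the forced switches by more than a cost of 1.0 the
  site is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix, PrePhase, SiteIndex
from .ibd import IBDSegment


@dataclass
class EndpointWeighting:
    """Sigmoid weight of a site's distance ``d`` (cM) to the nearer segment
    end: ``1 / (1 + exp(-slope * (d - d0)))``.

    ``d0`` is the distance at which the weight is 0.5; with the defaults
    (d0 = 1 cM, slope = 4 /cM) the weight is ~0.02 at the endpoint and
    >0.999 beyond 4 cM, matching the ~1 cM scale of endpoint overshoot on
    8 cM+ segments.
    """

    d0: float = 1.0
    slope: float = 4.0

    def weight(self, d):
        return 1.0 / (1.0 + np.exp(-self.slope * (np.asarray(d, dtype=float) - self.d0)))


def endpoint_weight(seg: IBDSegment, site_idx: int, sites: SiteIndex,
                    w: EndpointWeighting = EndpointWeighting()) -> float:
    """Weight of ``site_idx`` within ``seg`` (error if outside)."""
    if not (seg.start <= site_idx < seg.end):
        raise ValueError("site outside segment")
    cm = sites.cm
    d = min(cm[site_idx] - cm[seg.start], cm[seg.end - 1] - cm[site_idx])
    return float(w.weight(d))


@dataclass
class SplitConfig:
    weighting: EndpointWeighting = field(default_factory=EndpointWeighting)
    switch_trigger: float = 1.0     # weighted switches that trigger the lookahead
    lookahead_window: int = 20      # het sites examined on each flank
    lookahead_cost: float = 1.0     # ignore the site above this contradiction cost
    min_fragment_cm: float = 5.0    # fragments above this are retained for labeling


@dataclass
class Fragment:
    """A (piece of a) sided IBD segment produced by the group scan."""

    id: int
    seg_id: int                 # index into the input segment list
    other_id: str
    chrom: str
    start: int                  # global site index, inclusive
    end: int                    # exclusive
    side: int                   # chromosome-local parental side, 0 or 1
    cm: float


@dataclass
class GroupAssignment:
    """Output of the parental-group scan over the whole genome."""

    fragments: list[Fragment] = field(default_factory=list)
    breakpoints: list[tuple[int, int]] = field(default_factory=list)  # (seg_id, site)
    ignored_sites: list[int] = field(default_factory=list)
    #: at resolved proband-het sites: which allele sits on side A (else -1)
    orientation: np.ndarray | None = None
    #: per-site carried parity: 0 = pre-phase hapA allele on side A, 1 = flipped
    parity: np.ndarray | None = None
    #: seg_id -> (vote site idx array, vote allele array, vote weight array)
    seg_votes: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)
    n_het_sites: int = 0

    def fragments_of_segment(self, seg_id: int) -> list[Fragment]:
        return [f for f in self.fragments if f.seg_id == seg_id]


def _segment_votes(seg: IBDSegment, proband: np.ndarray, other: np.ndarray,
                   sites: SiteIndex, w: EndpointWeighting):
    """Vote sites (proband het, other hom), alleles and weights for one segment."""
    sl = slice(seg.start, seg.end)
    het = proband[sl] == 1
    hom = (other[sl] == 0) | (other[sl] == 2)
    rel = np.flatnonzero(het & hom)
    idx = rel + seg.start
    allele = (other[idx] == 2).astype(np.int8)
    cm = sites.cm
    d = np.minimum(cm[idx] - cm[seg.start], cm[seg.end - 1] - cm[idx])
    return idx, allele, w.weight(d)


def assign_parental_groups(proband_calls: np.ndarray, segments: list[IBDSegment],
                           g: GenotypeMatrix, prephase: PrePhase,
                           cfg: SplitConfig = SplitConfig()) -> GroupAssignment:
    """Run the parental-group scan chromosome by chromosome."""
    sites = g.sites
    out = GroupAssignment()
    out.orientation = np.full(sites.n_sites, -1, dtype=np.int8)
    out.parity = np.zeros(sites.n_sites, dtype=np.int8)
    seg_on_chrom: dict[str, list[int]] = {}
    for k, s in enumerate(segments):
        seg_on_chrom.setdefault(s.chrom, []).append(k)
        out.seg_votes[k] = _segment_votes(s, proband_calls, g.row(s.other_id),
                                          sites, cfg.weighting)
    out.n_het_sites = int((proband_calls == 1).sum())
    frag_id = 0
    for chrom, sl in sites.chrom_slices().items():
        frags = _scan_chromosome(chrom, sl, proband_calls, prephase,
                                 [ (k, segments[k]) for k in seg_on_chrom.get(chrom, []) ],
                                 out, cfg, sites)
        for f in frags:
            f.id = frag_id
            frag_id += 1
            out.fragments.append(f)
    return out


def _scan_chromosome(chrom: str, sl: slice, proband: np.ndarray, prephase: PrePhase,
                     segs: list[tuple[int, IBDSegment]], out: GroupAssignment,
                     cfg: SplitConfig, sites: SiteIndex) -> list[Fragment]:
    cm = sites.cm
    het_sites = np.flatnonzero(proband[sl] == 1) + sl.start
    # per-site vote lists
    votes_by_site: dict[int, list[tuple[int, int, float]]] = {}
    site_votes_of_seg: dict[int, dict[int, tuple[int, float]]] = {}
    for k, _seg in segs:
        idx, allele, wts = out.seg_votes[k]
        site_votes_of_seg[k] = {}
        for i, a, w in zip(idx, allele, wts):
            votes_by_site.setdefault(int(i), []).append((k, int(a), float(w)))
            site_votes_of_seg[k][int(i)] = (int(a), float(w))

    side: dict[int, int] = {k: -1 for k, _ in segs}
    frag_start: dict[int, int] = {k: s.start for k, s in segs}
    seg_by_id = dict(segs)
    raw_frags: dict[int, list[tuple[int, int, int]]] = {k: [] for k, _ in segs}
    parity = 0

    def default_oA(t: int) -> int:
        if prephase.hapA[t] != MISSING and prephase.hapA[t] + prephase.hapB[t] == 1:
            return int(prephase.hapA[t] if parity == 0 else prephase.hapB[t])
        return parity

    for ti, t in enumerate(het_sites):
        votes = votes_by_site.get(int(t), [])
        assigned = [(k, a, w) for (k, a, w) in votes if side[k] != -1]
        if not assigned:
            oA = default_oA(t)
        else:
            # stay-weight for each orientation choice of "allele on side A"
            stay = [0.0, 0.0]
            for k, a, w in assigned:
                # segment on side 0 stays iff its allele is the side-A allele
                stay[a if side[k] == 0 else 1 - a] += w
            if stay[0] > stay[1]:
                oA = 0
            elif stay[1] > stay[0]:
                oA = 1
            else:
                oA = default_oA(t)
        changed = [(k, a, w) for (k, a, w) in assigned
                   if (a if side[k] == 0 else 1 - a) != oA]
        change_w = sum(w for _, _, w in changed)
        if change_w >= cfg.switch_trigger and changed:
            cost = _lookahead_cost(ti, het_sites, changed, side,
                                   votes_by_site, site_votes_of_seg,
                                   cfg.lookahead_window)
            if cost > cfg.lookahead_cost:
                out.ignored_sites.append(int(t))
                continue
        # accept the site: break switching segments, assign newcomers
        for k, a, w in changed:
            raw_frags[k].append((frag_start[k], int(t), side[k]))
            frag_start[k] = int(t)
            side[k] = 1 - side[k]
            out.breakpoints.append((k, int(t)))
        for k, a, w in votes:
            if side[k] == -1:
                side[k] = 0 if a == oA else 1
        out.orientation[t] = oA
        if prephase.hapA[t] != MISSING and prephase.hapA[t] + prephase.hapB[t] == 1:
            parity = 0 if oA == prephase.hapA[t] else 1
        out.parity[t] = parity
    # forward-fill parity across the chromosome for downstream default phasing
    par = out.parity[sl]
    fill = 0
    for j in range(len(par)):
        gi = sl.start + j
        if proband[gi] == 1 and out.orientation[gi] != -1:
            fill = par[j]
        par[j] = fill
    # close fragments at segment ends
    frags: list[Fragment] = []
    for k, seg in segs:
        if side[k] != -1:
            raw_frags[k].append((frag_start[k], seg.end, side[k]))
        frags.extend(_postprocess_fragments(k, seg, raw_frags[k], cm, cfg))
    return frags


def _lookahead_cost(ti: int, het_sites: np.ndarray, changed, side,
                    votes_by_site, site_votes_of_seg, window: int) -> float:
    """Weighted mass of forced switches that the flanking windows contradict.

    For each segment the current site would flip, the 20 heterozygous sites
    on each flank vote on its side by pairwise allele agreement with
    currently-assigned segments; if the flanks prefer the current side, the
    flip is contradicted and the segment's (weighted) vote at the trigger
    site is added to the cost.
    """
    lo = max(0, ti - window)
    win = list(het_sites[lo:ti]) + list(het_sites[ti + 1: ti + 1 + window])
    cost = 0.0
    for k, _a, w_k in changed:
        s = side[k]
        keep = flip = 0.0
        sv = site_votes_of_seg[k]
        for u in win:
            av = sv.get(int(u))
            if av is None:
                continue
            a_u, w_u = av
            for j, a_j, w_j in votes_by_site.get(int(u), ()):
                if j == k or side[j] == -1:
                    continue
                implied = side[j] if a_j == a_u else 1 - side[j]
                if implied == s:
                    keep += w_u * w_j
                else:
                    flip += w_u * w_j
        if keep > flip:
            cost += w_k
    return cost


def _postprocess_fragments(seg_id: int, seg: IBDSegment,
                           pieces: list[tuple[int, int, int]], cm: np.ndarray,
                           cfg: SplitConfig) -> list[Fragment]:
    """Retention rule: every fragment longer than ``min_fragment_cm`` is
    kept, the longest fragment of a segment is always kept, and kept
    fragments separated by a single SNP are merged."""
    if not pieces:
        return []
    lengths = [float(cm[e - 1] - cm[s]) for s, e, _ in pieces]
    longest = int(np.argmax(lengths))
    kept = [(s, e, sd) for i, (s, e, sd) in enumerate(pieces)
            if i == longest or lengths[i] > cfg.min_fragment_cm]
    merged: list[list[int]] = []
    for s, e, sd in kept:
        if merged and merged[-1][2] == sd and s - merged[-1][1] <= 1:
            merged[-1][1] = e
        else:
            merged.append([s, e, sd])
    return [Fragment(-1, seg_id, seg.other_id, seg.chrom, s, e, sd,
                     float(cm[e - 1] - cm[s]))
            for s, e, sd in merged]
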