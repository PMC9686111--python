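"""Parental-group separation: endpoint weights, the site scan, breaking,
and the genotype-error lookahead."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ibdphase import (MISSING, EndpointWeighting, GenotypeMatrix, PrePhase,
                      SplitConfig, assign_parental_groups, endpoint_weight)
from ibdphase.ibd import IBDSegment

from conftest import uniform_panel


def _prephase(proband: np.ndarray) -> PrePhase:
    hapA = np.where(proband == 1, 0, proband // 2).astype(np.int8)
    hapB = np.where(proband == 1, 1, proband // 2).astype(np.int8)
    hapA[proband == MISSING] = 0
    hapB[proband == MISSING] = 0
    return PrePhase(hapA, hapB, proband == MISSING)


def scenario(proband, others: dict, segs, spacing=0.5):
    """GenotypeMatrix + IBDSegment list from per-individual call arrays."""
    proband = np.asarray(proband, np.int8)
    sites = uniform_panel(len(proband), spacing)
    samples = ["P"] + list(others)
    calls = np.vstack([proband] + [np.asarray(others[s], np.int8) for s in others])
    g = GenotypeMatrix(sites, samples, calls)
    cm = sites.cm
    segments = [IBDSegment(name, "1", s, e, float(cm[e - 1] - cm[s]),
                           float(cm[e - 1] - cm[s])) for name, s, e in segs]
    return g, segments, _prephase(proband)


class TestEndpointWeight:
    def setup_method(self):
        self.sites = uniform_panel(101, 0.1)  # 10 cM
        self.seg = IBDSegment("x", "1", 0, 101, 10.0, 10.0)

    def test_endpoint_weight_small(self):
        assert endpoint_weight(self.seg, 0, self.sites) <= 0.05

    def test_midpoint_of_sigmoid_at_d0(self):
        # site 10 is exactly 1.0 cM (= d0) from the left end
        assert endpoint_weight(self.seg, 10, self.sites) == pytest.approx(0.5)

    def test_interior_weight_saturates(self):
        # site 50 is 5 cM from both ends
        assert endpoint_weight(self.seg, 50, self.sites) >= 0.999

    def test_site_outside_segment_is_error(self):
        with pytest.raises(ValueError):
            endpoint_weight(IBDSegment("x", "1", 10, 20, 1, 1), 5, self.sites)

    @given(st.floats(0, 20), st.floats(0, 20))
    @settings(max_examples=50, deadline=None)
    def test_weight_monotone_in_distance(self, d1, d2):
        w = EndpointWeighting()
        lo, hi = sorted([d1, d2])
        assert w.weight(lo) <= w.weight(hi) + 1e-12


class TestGroupScan:
    def test_opposite_homozygotes_go_to_opposite_sides(self):
        n = 60
        g, segs, pre = scenario([1] * n,
                                {"u": [0] * n, "v": [2] * n},
                                [("u", 0, n), ("v", 0, n)])
        a = assign_parental_groups(g.row("P"), segs, g, pre)
        assert len(a.fragments) == 2
        assert a.fragments[0].side != a.fragments[1].side
        assert a.breakpoints == []

    def test_no_segments_follows_prephase_default(self):
        n = 30
        g, segs, pre = scenario([1] * n, {}, [])
        a = assign_parental_groups(g.row("P"), segs, g, pre)
        assert a.fragments == []
        het = np.flatnonzero(g.row("P") == 1)
        np.testing.assert_array_equal(a.orientation[het], pre.hapA[het])

    def test_ibd2_segment_never_assigned(self):
        """A segment heterozygous wherever the proband is heterozygous
        (IBD2) casts no votes and gets no side."""
        n = 60
        g, segs, pre = scenario([1] * n,
                                {"u": [0] * n, "w": [1] * n},
                                [("u", 0, n), ("w", 0, n)])
        a = assign_parental_groups(g.row("P"), segs, g, pre)
        assert {f.other_id for f in a.fragments} == {"u"}

    def test_flipped_half_breaks_once_and_matches_brute_force(self):
        """One segment whose genotypes flip allegiance halfway is broken
        there; the scan's orientation sequence attains the exhaustive
        minimum of weighted side changes."""
        n = 12
        rng = np.random.default_rng(7)
        hapA = rng.integers(0, 2, n)
        others = {}
        for name in ("a1", "a2"):
            others[name] = (2 * hapA).astype(int)          # side of hapA
        for name in ("b1", "b2"):
            others[name] = (2 * (1 - hapA)).astype(int)    # other side
        flip = (2 * np.where(np.arange(n) < n // 2, hapA, 1 - hapA)).astype(int)
        others["fl"] = flip
        segs = [(name, 0, n) for name in others]
        g, segments, pre = scenario([1] * n, others, segs, spacing=2.0)
        a = assign_parental_groups(g.row("P"), segments, g, pre)
        by_ind = {}
        for f in a.fragments:
            by_ind.setdefault(f.other_id, []).append(f)
        assert len(by_ind["fl"]) == 2
        assert by_ind["fl"][0].side != by_ind["fl"][1].side
        for name in ("a1", "a2", "b1", "b2"):
            assert len(by_ind[name]) == 1
        assert a.ignored_sites == []
        # exhaustive oracle over all orientation sequences
        votes = {k: dict(zip(a.seg_votes[k][0], zip(a.seg_votes[k][1],
                                                    a.seg_votes[k][2])))
                 for k in range(len(segments))}
        het = np.flatnonzero(g.row("P") == 1)

        def cost(seq):
            side, total = {}, 0.0
            for oA, t in zip(seq, het):
                for k, v in votes.items():
                    av = v.get(t)
                    if av is None:
                        continue
                    want = 0 if av[0] == oA else 1
                    if k in side and side[k] != want:
                        total += av[1]
                    side[k] = want
            return total

        best = min(cost(tuple(int(b) for b in np.binary_repr(m, len(het))))
                   for m in range(2 ** len(het)))
        scan_cost = cost(tuple(int(a.orientation[t]) for t in het))
        assert scan_cost == pytest.approx(best)

    def test_scan_is_deterministic(self, small_db):
        from ibdphase import IBDPhaseModel
        r1 = IBDPhaseModel(small_db.genotypes, small_db.proband).fit(seed=9)
        r2 = IBDPhaseModel(small_db.genotypes, small_db.proband).fit(seed=9)
        f1 = [(f.seg_id, f.start, f.end, f.side) for f in r1.assignment.fragments]
        f2 = [(f.seg_id, f.start, f.end, f.side) for f in r2.assignment.fragments]
        assert f1 == f2
        np.testing.assert_array_equal(r1.hapA, r2.hapA)


class TestLookahead:
    def _error_scenario(self, error_votes_all_same=True):
        """6 segments in two consistent camps; at one interior site every
        segment is homozygous for the same allele, as happens when the
        proband's homozygote is miscalled heterozygous."""
        n = 41
        rng = np.random.default_rng(3)
        hapA = rng.integers(0, 2, n)
        e = 20
        others = {}
        for i in range(3):
            others[f"a{i}"] = (2 * hapA).astype(int)
            others[f"b{i}"] = (2 * (1 - hapA)).astype(int)
        if error_votes_all_same:
            for i in range(3):
                others[f"b{i}"][e] = 2 * hapA[e]
        segs = [(name, 0, n) for name in others]
        return scenario([1] * n, others, segs, spacing=0.5), e

    def test_false_heterozygote_is_ignored(self):
        (g, segments, pre), e = self._error_scenario()
        a = assign_parental_groups(g.row("P"), segments, g, pre)
        assert e in a.ignored_sites
        assert a.breakpoints == []

    def test_consistent_het_not_ignored(self):
        (g, segments, pre), _e = self._error_scenario(error_votes_all_same=False)
        a = assign_parental_groups(g.row("P"), segments, g, pre)
        assert a.ignored_sites == []
        assert a.breakpoints == []

    def test_subthreshold_switch_breaks_without_lookahead(self):
        """A forced switch worth < 1.0 weighted segments is applied
        directly: the segment breaks and the site is not ignored."""
        n = 61
        hapA = np.ones(n, int)
        others = {"a": (2 * hapA).astype(int),
                  "b": (2 * (1 - hapA)).astype(int),
                  "c": (2 * hapA).astype(int)}
        # c's segment ends just after site 40: its vote there is weak
        others["c"][40] = 2 * (1 - hapA[40])
        segs = [("a", 0, n), ("b", 0, n), ("c", 0, 43)]
        g, segments, pre = scenario([1] * n, others, segs, spacing=0.5)
        cfg = SplitConfig(min_fragment_cm=0.0)
        a = assign_parental_groups(g.row("P"), segments, g, pre, cfg)
        assert a.ignored_sites == []
        assert any(k == 2 for k, _t in a.breakpoints)
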