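"""Phase emission: overrides, imputation, pre-phase defaults."""

import numpy as np
import pytest

from ibdphase import (MISSING, GenotypeMatrix, PhaseConfig, PrePhase,
                      phase_genome)
from ibdphase.cluster import Subcluster, Supercluster
from ibdphase.ibd import IBDSegment
from ibdphase.phaser import (GENOTYPE_OVERRIDE, IMPUTED_OVERRIDE,
                             PROV_BOTH_SIDES, PROV_ONE_SIDE, PROV_PREPHASE)
from ibdphase.split import Fragment, GroupAssignment

from conftest import uniform_panel

J = 50  # interior evaluation site (weight ~1 for a full-span fragment)


def phase_case(proband, prephase_haps, donors, n=101, spacing=0.1, cfg=None):
    """donors: list of (side, calls array, end_idx or None)."""
    proband = np.asarray(proband, np.int8)
    sites = uniform_panel(n, spacing)
    samples = ["P"] + [f"d{i}" for i in range(len(donors))]
    calls = np.vstack([proband] + [np.asarray(d[1], np.int8) for d in donors])
    g = GenotypeMatrix(sites, samples, calls)
    hapA, hapB = (np.asarray(h, np.int8) for h in prephase_haps)
    pre = PrePhase(hapA, hapB, proband == MISSING)
    a = GroupAssignment()
    a.parity = np.zeros(n, np.int8)
    segments, members = [], []
    for i, (side, _calls, end) in enumerate(donors):
        end = end or n
        cm = float(sites.cm[end - 1] - sites.cm[0])
        segments.append(IBDSegment(f"d{i}", "1", 0, end, cm, cm))
        a.fragments.append(Fragment(i, i, f"d{i}", "1", 0, end, side, cm))
        members.append((i, side))
    subs = [Subcluster(0, "1", members, (0, n))] if members else []
    sups = [Supercluster(0, [0], {0: 0}, 0.0)] if members else []
    ph = phase_genome(proband, pre, a, segments, subs, sups, g,
                      cfg or PhaseConfig())
    return ph


def _const(val, n=101, at=None, v2=None):
    arr = np.full(n, val, np.int8)
    if at is not None:
        arr[at] = v2
    return arr


class TestSiteLogic:
    def test_one_sided_evidence_overrides_imputed_call(self):
        """Original call missing, pre-phase imputed 0|0; >=0.1 weighted
        evidence for allele 1 on side A flips hapA only."""
        proband = _const(0, at=J, v2=MISSING)
        ph = phase_case(proband, (_const(0), _const(0)),
                        [(0, _const(2), None)])
        assert (ph.hapA[J], ph.hapB[J]) == (1, 0)
        assert (J, MISSING, 1, IMPUTED_OVERRIDE) in ph.corrections
        assert ph.provenance[J] == PROV_ONE_SIDE

    def test_two_sided_evidence_overrides_genotype_call(self):
        """Hom-ref original, ~2.0 weighted for allele 1 on A and ~2.0 for
        allele 0 on B -> emitted 1|0 with a genotype override."""
        ph = phase_case(_const(0), (_const(0), _const(0)),
                        [(0, _const(2), None), (0, _const(2), None),
                         (1, _const(0), None), (1, _const(0), None)])
        assert (ph.hapA[J], ph.hapB[J]) == (1, 0)
        assert (J, 0, 1, GENOTYPE_OVERRIDE) in ph.corrections
        assert ph.provenance[J] == PROV_BOTH_SIDES

    def test_het_below_overlap_threshold_keeps_prephase(self):
        """A het whose only evidence sits at a segment endpoint (weight
        ~0.02 < 0.1) keeps the pre-phase orientation."""
        donor = _const(2)
        ph = phase_case(_const(1), (_const(1), _const(0)),
                        [(0, donor, J + 1)])  # segment ends exactly at J
        assert (ph.hapA[J], ph.hapB[J]) == (1, 0)  # pre-phase orientation
        assert ph.provenance[J] == PROV_PREPHASE
        assert ph.corrections == []

    def test_het_oriented_by_moderate_one_sided_evidence(self):
        """Evidence ~0.5 (site 1 cM from a segment end) exceeds the 0.1
        orientation threshold: the het is oriented, genotype unchanged."""
        ph = phase_case(_const(1), (_const(0), _const(1)),
                        [(0, _const(2), J + 11)])  # J is 1.0 cM from the end
        assert (ph.hapA[J], ph.hapB[J]) == (1, 0)
        assert ph.provenance[J] == PROV_ONE_SIDE
        assert ph.corrections == []

    def test_het_with_concordant_two_sided_evidence(self):
        ph = phase_case(_const(1), (_const(0), _const(1)),
                        [(0, _const(2), None), (1, _const(0), None)])
        assert (ph.hapA[J], ph.hapB[J]) == (1, 0)
        assert ph.provenance[J] == PROV_BOTH_SIDES
        assert ph.corrections == []

    def test_one_sided_evidence_never_changes_a_het_genotype(self):
        """Strong one-sided evidence orients but does not rewrite a het."""
        ph = phase_case(_const(1), (_const(0), _const(1)),
                        [(0, _const(2), None), (0, _const(2), None)])
        assert int(ph.hapA[J]) + int(ph.hapB[J]) == 1
        assert ph.corrections == []


class TestGenomeLevel:
    def test_zero_ibd_returns_prephase_exactly(self):
        pre = (_const(0), _const(1))
        ph = phase_case(_const(1), pre, [])
        np.testing.assert_array_equal(ph.hapA, pre[0])
        np.testing.assert_array_equal(ph.hapB, pre[1])
        assert (ph.provenance == PROV_PREPHASE).all()
        assert ph.corrections == []

    def test_infinite_thresholds_disable_corrections(self):
        cfg = PhaseConfig(genotype_override=np.inf, impute_override=np.inf)
        proband = _const(0, at=J, v2=MISSING)
        ph = phase_case(proband, (_const(0), _const(0)),
                        [(0, _const(2), None), (1, _const(2), None)], cfg=cfg)
        assert ph.corrections == []

    def test_prephase_default_sites_reproduce_original_call(self, small_db):
        from ibdphase import IBDPhaseModel
        res = IBDPhaseModel(small_db.genotypes, small_db.proband).fit(seed=2)
        ph = res.phased
        default = ph.provenance == PROV_PREPHASE
        orig = res.proband_calls
        ok = default & (orig != MISSING)
        np.testing.assert_array_equal(ph.hapA[ok] + ph.hapB[ok], orig[ok])

    def test_more_evidence_never_increases_default_sites(self, small_db):
        from ibdphase import IBDPhaseModel, detect_all
        g = small_db.genotypes
        segs, _ = detect_all(small_db.proband, g)
        half = segs[: len(segs) // 2]
        full = IBDPhaseModel(g, small_db.proband, segments=segs).fit(seed=0)
        part = IBDPhaseModel(g, small_db.proband, segments=half).fit(seed=0)
        n_full = int((full.phased.provenance == PROV_PREPHASE).sum())
        n_part = int((part.phased.provenance == PROV_PREPHASE).sum())
        assert n_full <= n_part

    def test_emitted_hets_are_valid_diploid_calls(self, small_db):
        from ibdphase import IBDPhaseModel
        res = IBDPhaseModel(small_db.genotypes, small_db.proband).fit(seed=2)
        ph = res.phased
        present = (ph.hapA != MISSING) & (ph.hapB != MISSING)
        assert set(np.unique(ph.hapA[present] + ph.hapB[present])) <= {0, 1, 2}
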