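"""Genome-wide phase emission from sided IBD evidence.

Once fragments carry global parental sides (A/B), every panel site
collects two weighted allele tallies — one per side — from the database
individuals homozygous there.  The emitted haplotype pair is then:

* the two sides' majority alleles, where both sides have enough weight;
* one side's allele plus the pre-phase complement, where only one side
  is informative (a *homozygous* original call is only overridden here);
* the pre-phase call and orientation, where IBD says nothing.

Weighted evidence of 1.0 may override a non-missing genotype call; 0.1
suffices to override a call imputed by the pre-phase (the original call
was missing) or to orient an existing heterozygote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix, PrePhase
from .ibd import IBDSegment
from .split import EndpointWeighting, GroupAssignment
from .cluster import Subcluster, Supercluster, fragment_global_sides

PROV_PREPHASE = 0
PROV_ONE_SIDE = 1
PROV_BOTH_SIDES = 2

IMPUTED_OVERRIDE = "imputed_override"
GENOTYPE_OVERRIDE = "genotype_override"


@dataclass
class PhaseConfig:
    genotype_override: float = 1.0   # weighted segments to override a genotype call
    impute_override: float = 0.1     # ... to override an imputed call / orient a het
    overlap_threshold: float = 0.1   # side counts as informative at/above this
    weighting: EndpointWeighting = field(default_factory=EndpointWeighting)


@dataclass
class PhasedGenome:
    hapA: np.ndarray                 # int8 in {0,1,MISSING}
    hapB: np.ndarray
    provenance: np.ndarray           # int8, PROV_* codes
    corrections: list[tuple[int, int, int, str]] = field(default_factory=list)
    conflicts: list[int] = field(default_factory=list)
    #: per-site weighted evidence totals for sides A and B
    evidence_A: np.ndarray | None = None
    evidence_B: np.ndarray | None = None

    def genotype(self) -> np.ndarray:
        g = self.hapA.astype(np.int8) + self.hapB.astype(np.int8)
        g[(self.hapA == MISSING) | (self.hapB == MISSING)] = MISSING
        return g


def _evidence_arrays(n_sites: int, assignment: GroupAssignment,
                     segments: list[IBDSegment], sides: dict[int, int],
                     g: GenotypeMatrix, w: EndpointWeighting):
    """Weighted allele tallies per global side over all panel sites."""
    tallies = np.zeros((2, 2, n_sites))  # [side, allele]
    cm = g.sites.cm
    for f in assignment.fragments:
        seg = segments[f.seg_id]
        other = g.row(f.other_id)
        sl = slice(f.start, f.end)
        calls = other[sl]
        pos = np.arange(f.start, f.end)
        d = np.minimum(cm[pos] - cm[seg.start], cm[seg.end - 1] - cm[pos])
        wt = w.weight(d)
        side = sides[f.id]
        for allele, hom in ((0, calls == 0), (1, calls == 2)):
            t = tallies[side, allele, sl.start:sl.stop]
            t[hom] += wt[hom]
    return tallies


def _chromosome_flips(sites, subclusters: list[Subcluster],
                      superclusters: list[Supercluster],
                      assignment: GroupAssignment) -> dict[str, int]:
    """Per-chromosome bit mapping the scan's local frame to the global frame,
    taken from the dominant (largest fragment-cM) subcluster on the
    chromosome."""
    orient: dict[int, int] = {}
    for sup in superclusters:
        orient.update(sup.orientation)
    frag_cm = {f.id: f.cm for f in assignment.fragments}
    best: dict[str, tuple[float, int]] = {}
    for sc in subclusters:
        mass = sum(frag_cm.get(fid, 0.0) for fid, _ in sc.members)
        if sc.chrom not in best or mass > best[sc.chrom][0]:
            best[sc.chrom] = (mass, orient.get(sc.id, 0))
    return {c: bit for c, (_, bit) in best.items()}


def phase_genome(proband_calls: np.ndarray, prephase: PrePhase,
                 assignment: GroupAssignment, segments: list[IBDSegment],
                 subclusters: list[Subcluster], superclusters: list[Supercluster],
                 g: GenotypeMatrix,
                 cfg: PhaseConfig = PhaseConfig()) -> PhasedGenome:
    n = g.sites.n_sites
    sides = fragment_global_sides(subclusters, superclusters)
    tallies = _evidence_arrays(n, assignment, segments, sides, g, cfg.weighting)
    flips = _chromosome_flips(g.sites, subclusters, superclusters, assignment)

    # pre-phase alleles mapped into the global frame
    eff = assignment.parity.copy() if assignment.parity is not None else np.zeros(n, np.int8)
    for chrom, sl in g.sites.chrom_slices().items():
        if flips.get(chrom, 0):
            eff[sl] ^= 1
    preA = np.where(eff == 0, prephase.hapA, prephase.hapB).astype(np.int8)
    preB = np.where(eff == 0, prephase.hapB, prephase.hapA).astype(np.int8)

    hapA, hapB = preA.copy(), preB.copy()
    prov = np.zeros(n, np.int8)
    out = PhasedGenome(hapA, hapB, prov)

    sA = tallies[0].sum(axis=0)
    sB = tallies[1].sum(axis=0)
    out.evidence_A, out.evidence_B = sA, sB
    active = np.flatnonzero((sA > 0) | (sB > 0))
    thr_ov = cfg.overlap_threshold
    for j in active:
        wA0, wA1 = tallies[0, 0, j], tallies[0, 1, j]
        wB0, wB1 = tallies[1, 0, j], tallies[1, 1, j]
        ovA, ovB = sA[j] >= thr_ov, sB[j] >= thr_ov
        if ovA and ovB:
            prov[j] = PROV_BOTH_SIDES
        elif ovA or ovB:
            prov[j] = PROV_ONE_SIDE
        else:
            continue
        aA = 1 if wA1 > wA0 else (0 if wA0 > wA1 else -1)
        aB = 1 if wB1 > wB0 else (0 if wB0 > wB1 else -1)
        if (wA0 > 0 and wA1 > 0) or (wB0 > 0 and wB1 > 0):
            out.conflicts.append(int(j))
        orig = int(proband_calls[j])
        if orig == MISSING:
            req = cfg.impute_override
            strongA = sA[j] >= req and aA != -1
            strongB = sB[j] >= req and aB != -1
            old = (int(preA[j]), int(preB[j]))
            if strongA and strongB:
                hapA[j], hapB[j] = aA, aB
            elif strongA:
                hapA[j] = aA
            elif strongB:
                hapB[j] = aB
            if (int(hapA[j]), int(hapB[j])) != old:
                out.corrections.append((int(j), MISSING, int(hapA[j] + hapB[j]),
                                        IMPUTED_OVERRIDE))
        elif orig == 1:
            strongA = sA[j] >= cfg.genotype_override and aA != -1
            strongB = sB[j] >= cfg.genotype_override and aB != -1
            if strongA and strongB and aA + aB != 1:
                hapA[j], hapB[j] = aA, aB  # both sides agree on a homozygote
                out.corrections.append((int(j), 1, int(aA + aB), GENOTYPE_OVERRIDE))
                continue
            # orient the het: pick the arrangement best supported by evidence
            s1 = wA1 + wB0   # hapA=1 | hapB=0
            s0 = wA0 + wB1   # hapA=0 | hapB=1
            if max(s1, s0) >= cfg.impute_override and s1 != s0:
                hapA[j], hapB[j] = (1, 0) if s1 > s0 else (0, 1)
            else:
                prov[j] = PROV_PREPHASE
                if preA[j] == MISSING or preB[j] == MISSING or preA[j] + preB[j] != 1:
                    hapA[j], hapB[j] = 0, 1
        else:
            ha = orig // 2
            strongA = sA[j] >= cfg.genotype_override and aA != -1
            strongB = sB[j] >= cfg.genotype_override and aB != -1
            if strongA and strongB and aA + aB != orig:
                hapA[j], hapB[j] = aA, aB
                out.corrections.append((int(j), orig, int(aA + aB), GENOTYPE_OVERRIDE))
            elif strongA and not strongB and aA != ha:
                hapA[j], hapB[j] = aA, ha
                out.corrections.append((int(j), orig, int(aA + ha), GENOTYPE_OVERRIDE))
            elif strongB and not strongA and aB != ha:
                hapA[j], hapB[j] = ha, aB
                out.corrections.append((int(j), orig, int(ha + aB), GENOTYPE_OVERRIDE))
            else:
                hapA[j], hapB[j] = ha, ha
    # pre-phase-default sites must reproduce the original call
    default = np.flatnonzero(prov == PROV_PREPHASE)
    bad = default[(proband_calls[default] != MISSING)
                  & (hapA[default] + hapB[default] != proband_calls[default])]
    for j in bad:
        orig = int(proband_calls[j])
        if orig == 1:
            hapA[j], hapB[j] = 0, 1
        else:
            hapA[j] = hapB[j] = orig // 2
    return out
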