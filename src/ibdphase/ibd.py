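"""IBD segment and IBD2-run detection from unphased genotypes.

Two individuals are IBD over a stretch of the genome if they share at
least one allele at every site in it.  On unphased diploid data the only
sites that can contradict sharing are *opposite homozygotes* (one
individual hom-ref, the other hom-alt), so candidate segments are the
maximal conflict-free runs between opposite-homozygote sites.  A run is
reported when (i) it spans at least ``min_cm`` (default 8 cM) and (ii) it
still spans at least ``min_trimmed_cm`` (default 5 cM) after discarding
every inter-SNP gap larger than ``max_gap_cm`` (default 0.05 cM) — the
density criterion that rejects segments supported by sparse SNPs.

The scan is word-level bitwise: per individual, packed bitplanes mark the
hom-ref / hom-alt / missing sites, and the conflict mask for a pair is
``(refA & altB) | (altA & refB)`` over packed words.  Missing calls never
conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix, SiteIndex


@dataclass
class DetectConfig:
    min_cm: float = 8.0          # minimum genetic length of a reported segment
    min_trimmed_cm: float = 5.0  # minimum density-trimmed length
    max_gap_cm: float = 0.05     # inter-SNP gaps above this are discarded when trimming
    min_ibd2_cm: float = 5.0     # minimum length of a reported IBD2 run


@dataclass
class IBDSegment:
    """A half-open run of panel sites shared IBD with one database individual."""

    other_id: str
    chrom: str
    start: int                  # global site index, inclusive
    end: int                    # global site index, exclusive
    cm_length: float
    trimmed_cm: float

    def overlaps(self, other: "IBDSegment") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class Ibd2Run:
    other_id: str
    chrom: str
    start: int
    end: int
    cm_length: float


@dataclass
class RelationshipStats:
    """Genome-wide sharing summary for one proband/database-individual pair."""

    other_id: str
    total_shared_cm: float      # summed cM of detected segments (IBD1 or IBD2)
    ibd2_run_fraction: float    # fraction of genome cM covered by IBD2 runs
    ibd1_rate: float            # fraction of comparable sites sharing >= 1 allele
    n_segments: int


def homozygosity_bitmaps(g: GenotypeMatrix, individual: str
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Packed (hom_ref, hom_alt, missing) bitplanes for one individual."""
    row = g.row(individual)
    return (np.packbits(row == 0), np.packbits(row == 2),
            np.packbits(row == MISSING))


def _runs_between(break_idx: np.ndarray, start: int, stop: int):
    """Yield (first, last) inclusive site bounds of runs in [start, stop)
    after removing the break sites."""
    prev = start
    for b in break_idx:
        if b > prev:
            yield prev, b - 1
        prev = b + 1
    if stop > prev:
        yield prev, stop - 1


def _trimmed_prefix(cm: np.ndarray, max_gap: float) -> np.ndarray:
    """Prefix sums of inter-site gaps clipped to zero above ``max_gap``."""
    gaps = np.diff(cm)
    gaps = np.where(gaps <= max_gap, gaps, 0.0)
    out = np.zeros(len(cm))
    np.cumsum(gaps, out=out[1:])
    return out


def detect_ibd_segments(proband: str, other: str, g: GenotypeMatrix,
                        cfg: DetectConfig = DetectConfig(),
                        site_mask: np.ndarray | None = None) -> list[IBDSegment]:
    """Detect IBD segments between ``proband`` and ``other``.

    ``site_mask`` optionally restricts detection to a subset of panel
    sites (used by the perturbation experiment, where held-out sites
    are scored for imputation/correction); segment coordinates are still
    reported on the full panel.
    """
    pr, pa, _ = homozygosity_bitmaps(g, proband)
    orr, oa, _ = homozygosity_bitmaps(g, other)
    conflict_bits = (pr & oa) | (pa & orr)
    conflict = np.unpackbits(conflict_bits)[: g.sites.n_sites].astype(bool)
    if site_mask is not None:
        conflict &= site_mask
    return segments_from_conflicts(other, conflict, g.sites, cfg)


def segments_from_conflicts(other_id: str, conflict: np.ndarray,
                            sites: SiteIndex, cfg: DetectConfig) -> list[IBDSegment]:
    """Turn a per-site conflict mask into length/density-filtered segments."""
    out: list[IBDSegment] = []
    cm = sites.cm
    for chrom, sl in sites.chrom_slices().items():
        trim = _trimmed_prefix(cm[sl], cfg.max_gap_cm)
        breaks = np.flatnonzero(conflict[sl]) + sl.start
        for first, last in _runs_between(breaks, sl.start, sl.stop):
            length = float(cm[last] - cm[first])
            if length < cfg.min_cm:
                continue
            trimmed = float(trim[last - sl.start] - trim[first - sl.start])
            if trimmed < cfg.min_trimmed_cm:
                continue
            out.append(IBDSegment(other_id, chrom, first, last + 1, length, trimmed))
    return out


def detect_ibd2_runs(proband: str, other: str, g: GenotypeMatrix,
                     cfg: DetectConfig = DetectConfig()) -> list[Ibd2Run]:
    """Maximal runs of identical genotypes (IBD2) of at least ``min_ibd2_cm``.

    Missing calls neither break a run nor extend its measured ends: a run
    is delimited by sites where both calls are present and equal.
    """
    a = g.row(proband)
    b = g.row(other)
    present = (a != MISSING) & (b != MISSING)
    differ = present & (a != b)
    same = present & (a == b)
    out: list[Ibd2Run] = []
    cm = g.sites.cm
    for chrom, sl in g.sites.chrom_slices().items():
        breaks = np.flatnonzero(differ[sl]) + sl.start
        for first, last in _runs_between(breaks, sl.start, sl.stop):
            inf = np.flatnonzero(same[first:last + 1])
            if not len(inf):
                continue
            lo, hi = first + inf[0], first + inf[-1]
            length = float(cm[hi] - cm[lo])
            if length >= cfg.min_ibd2_cm:
                out.append(Ibd2Run(other, chrom, lo, hi + 1, length))
    return out


def relationship_stats(proband: str, other: str, g: GenotypeMatrix,
                       segments: list[IBDSegment],
                       runs: list[Ibd2Run]) -> RelationshipStats:
    """Summarise genome-wide sharing for one pair.

    ``ibd1_rate`` is the fraction of sites, comparable in both individuals,
    that share at least one allele (i.e. are not opposite homozygotes);
    ``ibd2_run_fraction`` is the genome-cM fraction covered by IBD2 runs.
    """
    a = g.row(proband)
    b = g.row(other)
    present = (a != MISSING) & (b != MISSING)
    n_comp = int(present.sum())
    if n_comp == 0:
        raise ValueError("no comparable sites between pair")
    opp = present & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))
    genome = g.sites.genome_cm()
    return RelationshipStats(
        other_id=other,
        total_shared_cm=float(sum(s.cm_length for s in segments)),
        ibd2_run_fraction=float(sum(r.cm_length for r in runs)) / genome if genome else 0.0,
        ibd1_rate=1.0 - opp.sum() / n_comp,
        n_segments=len(segments),
    )


def detect_all(proband: str, g: GenotypeMatrix, others: list[str] | None = None,
               cfg: DetectConfig = DetectConfig(),
               site_mask: np.ndarray | None = None
               ) -> tuple[list[IBDSegment], dict[str, RelationshipStats]]:
    """Detect segments against every database individual; return segments
    plus per-individual relationship statistics (IBD2 runs are computed only
    for pairs that share any segment, as only those can be close family)."""
    if others is None:
        others = [s for s in g.samples if s != proband]
    segments: list[IBDSegment] = []
    stats: dict[str, RelationshipStats] = {}
    for o in others:
        segs = detect_ibd_segments(proband, o, g, cfg, site_mask)
        if not segs:
            continue
        runs = detect_ibd2_runs(proband, o, g, cfg)
        segments.extend(segs)
        stats[o] = relationship_stats(proband, o, g, segs, runs)
    return segments, stats
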