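"""Phase-accuracy metrics against trio truth.

All metrics use only SNPs where the phase of the proband's heterozygote
can be unambiguously inferred from the parents — at least one parent is
homozygous (and the trio is Mendelian-consistent there).

* **Global phase error** — fraction of resolvable heterozygous sites whose
  allele-to-parent placement disagrees with trio phase, keeping one
  haplotype assigned to one parent across the whole genome but taking the
  better of the two haplotype<->parent assignments.
* **Switch error rate** — how often the phase of a heterozygous SNP
  differs from that of the previous heterozygous SNP, relative to trio
  phase.
* **% SNPs in 1 cM+ runs** — proportion of sites inside maximal
  switch-free runs spanning at least 1 cM (local accuracy that does not
  penalize isolated badly-phased pockets).
* **Segment assignment error** — cM-weighted fraction of sided IBD
  fragments whose parental side disagrees with the parent that actually
  shares that DNA, again under the better global side<->parent mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, SiteIndex


@dataclass
class TrioTruth:
    """Parental genotype vectors; phase truth exists where a parent is hom."""

    mother: np.ndarray
    father: np.ndarray

    def resolvable_mask(self) -> np.ndarray:
        m_hom = (self.mother == 0) | (self.mother == 2)
        f_hom = (self.father == 0) | (self.father == 2)
        return m_hom | f_hom


def resolve_trio(proband_calls: np.ndarray, trio: TrioTruth
                 ) -> tuple[np.ndarray, np.ndarray]:
    """(site indices, maternal allele) at proband heterozygotes whose phase
    the trio resolves consistently."""
    het = proband_calls == 1
    m, f = trio.mother, trio.father
    m_hom = (m == 0) | (m == 2)
    f_hom = (f == 0) | (f == 2)
    idx = np.flatnonzero(het & (m_hom | f_hom))
    maternal = np.full(len(idx), -1, np.int8)
    mh, fh = m_hom[idx], f_hom[idx]
    ma = (m[idx] // 2).astype(np.int8)
    fa = (f[idx] // 2).astype(np.int8)
    # mother hom: maternal allele is hers; father must be able to supply the other
    maternal[mh] = ma[mh]
    only_f = ~mh & fh
    maternal[only_f] = 1 - fa[only_f]
    consistent = np.ones(len(idx), bool)
    both = mh & fh
    consistent[both] = ma[both] + fa[both] == 1
    return idx[consistent], maternal[consistent]


def _states(hapA: np.ndarray, hapB: np.ndarray, idx: np.ndarray,
            maternal: np.ndarray):
    """Per-site agree/disagree state (hapA carries the maternal allele) at
    resolvable sites with a valid emitted heterozygote; invalid sites are
    returned separately."""
    a, b = hapA[idx], hapB[idx]
    valid = (a != MISSING) & (b != MISSING) & (a + b == 1)
    return idx[valid], (a[valid] == maternal[valid]), int((~valid).sum())


def global_phase_error(hapA: np.ndarray, hapB: np.ndarray,
                       proband_calls: np.ndarray, trio: TrioTruth) -> float:
    """Percent; invalid/missing emitted calls at resolvable het sites count
    as errors under both assignments (conservative)."""
    idx, maternal = resolve_trio(proband_calls, trio)
    if not len(idx):
        raise ValueError("no trio-resolvable heterozygous sites")
    _vidx, agree, n_invalid = _states(hapA, hapB, idx, maternal)
    n = len(idx)
    e1 = (~agree).sum() + n_invalid
    e2 = agree.sum() + n_invalid
    return 100.0 * min(e1, e2) / n


def switch_error_rate(hapA: np.ndarray, hapB: np.ndarray,
                      proband_calls: np.ndarray, trio: TrioTruth) -> float:
    """Percent of transitions between agree/disagree across consecutive
    resolvable heterozygous sites (genome order), over n-1 transitions."""
    idx, maternal = resolve_trio(proband_calls, trio)
    _vidx, agree, _ninv = _states(hapA, hapB, idx, maternal)
    if len(agree) < 2:
        raise ValueError("need at least two resolvable heterozygous sites")
    return 100.0 * np.count_nonzero(np.diff(agree)) / (len(agree) - 1)


def pct_snps_in_1cm_runs(hapA: np.ndarray, hapB: np.ndarray,
                         proband_calls: np.ndarray, trio: TrioTruth,
                         sites: SiteIndex, min_run_cm: float = 1.0) -> float:
    """Percent of resolvable het sites inside switch-free runs >= 1 cM.

    Runs are bounded by chromosome ends and by phase switches.
    """
    idx, maternal = resolve_trio(proband_calls, trio)
    vidx, agree, _ninv = _states(hapA, hapB, idx, maternal)
    if not len(vidx):
        return 0.0
    cm = sites.cm
    chrom = sites.chrom[vidx]
    n_in = 0
    start = 0
    for i in range(1, len(vidx) + 1):
        boundary = (i == len(vidx) or agree[i] != agree[i - 1]
                    or chrom[i] != chrom[i - 1])
        if boundary:
            if cm[vidx[i - 1]] - cm[vidx[start]] >= min_run_cm:
                n_in += i - start
            start = i
    return 100.0 * n_in / len(vidx)


def segment_assignment_error(labeled: list[tuple[float, int, int]],
                             cm_weighted: bool = True) -> float:
    """Percent of fragment mass on the wrong parental side.

    ``labeled`` holds (fragment cM, assigned global side 0/1, true parental
    side 0/1 or -1 if unknown); entries with unknown truth are skipped.
    The better of the two global side <-> parent mappings is used.
    """
    known = [(cm if cm_weighted else 1.0, s, t) for cm, s, t in labeled if t in (0, 1)]
    if not known:
        raise ValueError("no truth-matchable fragments")
    total = sum(w for w, _s, _t in known)
    e1 = sum(w for w, s, t in known if s != t)
    return 100.0 * min(e1, total - e1) / total
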