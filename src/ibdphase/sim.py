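"""Synthetic genotype databases with known pedigrees and IBD truth.

Founder haplotypes are drawn site-independently from an allele-frequency
spectrum; each meiosis places Poisson(L/100) crossovers uniformly (in cM)
per chromosome of genetic length L, with no interference.  Transmission
tracks record which founder haplotype every position descends from, so
true IBD between any two individuals — and the parental origin of any
shared haplotype — is available exactly.

A database-builder assembles a proband with relatives at chosen degrees
(grandparents, aunts/uncles, first and second cousins, optionally a twin,
full sibling or nephew) plus unrelated individuals, so IBD coverage can
be dialed.  Genotype perturbation (missingness and het<->hom call errors)
matches the error model used in evaluation: 1% missing, 0.2% errors by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix, PrePhase, SiteIndex
from .ibd import IBDSegment


@dataclass
class SimConfig:
    n_chrom: int = 10
    chrom_cm: float = 100.0
    spacing_cm: float = 0.02       # mimics dense-array SNP spacing
    freq_low: float = 0.05         # founder alt-allele frequency range
    freq_high: float = 0.5
    missing_rate: float = 0.01
    error_rate: float = 0.002
    n_founders: int = 20
    n_generations: int = 2
    seed: int = 0


@dataclass
class SimTruth:
    sites: SiteIndex
    haplotypes: dict[str, np.ndarray]  # id -> (2, n_sites) int8; row 0 maternal
    tracks: dict[str, np.ndarray]      # id -> (2, n_sites) int32 founder-hap labels
    parents: dict[str, tuple[str, str] | None]  # id -> (mother, father)

    def genotype(self, individual: str) -> np.ndarray:
        h = self.haplotypes[individual]
        return (h[0] + h[1]).astype(np.int8)


def make_genetic_map(n_chrom: int, chrom_cm: float, spacing_cm: float) -> SiteIndex:
    """Evenly spaced SNP panel; physical position = 1 cM per Mb."""
    chroms, poss, cms = [], [], []
    for c in range(n_chrom):
        n = int(round(chrom_cm / spacing_cm)) + 1
        cm = np.arange(n) * spacing_cm
        chroms.extend([str(c + 1)] * n)
        poss.append((cm * 1e4).astype(np.int64) * 100 + 1)
        cms.append(cm)
    return SiteIndex(np.array(chroms, dtype=object),
                     np.concatenate(poss), np.concatenate(cms))


class PedigreeSimulator:
    """Incrementally grow a pedigree over a fixed map and frequency spectrum."""

    def __init__(self, cfg: SimConfig, sites: SiteIndex | None = None,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg
        self.sites = sites if sites is not None else make_genetic_map(
            cfg.n_chrom, cfg.chrom_cm, cfg.spacing_cm)
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.freqs = self.rng.uniform(cfg.freq_low, cfg.freq_high, self.sites.n_sites)
        self.truth = SimTruth(self.sites, {}, {}, {})
        self._next_label = 0

    def add_founder(self, name: str) -> str:
        n = self.sites.n_sites
        haps = (self.rng.random((2, n)) < self.freqs).astype(np.int8)
        tracks = np.empty((2, n), np.int32)
        tracks[0] = self._next_label
        tracks[1] = self._next_label + 1
        self._next_label += 2
        self.truth.haplotypes[name] = haps
        self.truth.tracks[name] = tracks
        self.truth.parents[name] = None
        return name

    def _gamete(self, parent: str) -> tuple[np.ndarray, np.ndarray]:
        haps = self.truth.haplotypes[parent]
        tracks = self.truth.tracks[parent]
        hap = np.empty(self.sites.n_sites, np.int8)
        trk = np.empty(self.sites.n_sites, np.int32)
        for _c, sl in self.sites.chrom_slices().items():
            cm = self.sites.cm[sl]
            L = cm[-1] - cm[0]
            n_x = self.rng.poisson(L / 100.0)
            xs = np.sort(self.rng.uniform(cm[0], cm[-1], n_x))
            which = (self.rng.integers(0, 2) + np.searchsorted(xs, cm, side="right")) % 2
            hap[sl] = np.where(which == 0, haps[0, sl], haps[1, sl])
            trk[sl] = np.where(which == 0, tracks[0, sl], tracks[1, sl])
        return hap, trk

    def add_child(self, name: str, mother: str, father: str) -> str:
        hm, tm = self._gamete(mother)
        hf, tf = self._gamete(father)
        self.truth.haplotypes[name] = np.stack([hm, hf])
        self.truth.tracks[name] = np.stack([tm, tf])
        self.truth.parents[name] = (mother, father)
        return name

    def add_twin(self, name: str, of: str) -> str:
        self.truth.haplotypes[name] = self.truth.haplotypes[of].copy()
        self.truth.tracks[name] = self.truth.tracks[of].copy()
        self.truth.parents[name] = self.truth.parents[of]
        return name

    def genotypes(self, individuals: list[str] | None = None) -> GenotypeMatrix:
        ids = individuals if individuals is not None else list(self.truth.haplotypes)
        calls = np.stack([self.truth.genotype(i) for i in ids])
        return GenotypeMatrix(self.sites, list(ids), calls)


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Random-mating population: monogamous couples, two children each.

    With ``n_generations == 0`` only founders are produced and every
    transmission track is the founder's own label.
    """
    sim = PedigreeSimulator(cfg)
    gen = [sim.add_founder(f"G0_I{i}") for i in range(cfg.n_founders)]
    for g in range(1, cfg.n_generations + 1):
        order = list(sim.rng.permutation(gen))
        nxt = []
        for i in range(0, len(order) - 1, 2):
            for c in range(2):
                nxt.append(sim.add_child(f"G{g}_I{len(nxt)}", order[i], order[i + 1]))
        gen = nxt
    return sim.genotypes(), sim.truth


# ---------------------------------------------------------------------------
# database builder

@dataclass
class DatabaseSpec:
    """Relative counts per parental side for the proband's database."""

    n_aunts_per_side: int = 3
    n_cousins_per_aunt: int = 2
    n_second_per_side: int = 3     # second cousins (via a great-uncle line)
    include_grandparents: bool = True
    include_sibling: bool = False
    include_twin: bool = False
    include_nephew: bool = False   # child of a full sibling: descends from both parents
    n_unrelated: int = 10


@dataclass
class SimDatabase:
    genotypes: GenotypeMatrix      # proband + database (parents excluded)
    truth: SimTruth
    sim: PedigreeSimulator
    proband: str = "proband"
    mother: str = "mother"
    father: str = "father"
    db_ids: list[str] = field(default_factory=list)
    relatives: dict[str, str] = field(default_factory=dict)  # id -> relationship


def make_database(cfg: SimConfig, spec: DatabaseSpec = DatabaseSpec(),
                  seed: int | None = None) -> SimDatabase:
    """A proband, one-sided relatives on each side, optional two-sided
    relatives, and unrelated individuals.  Parents are simulated (for trio
    truth) but excluded from the database genotypes."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sim = PedigreeSimulator(cfg, rng=rng)
    rel: dict[str, str] = {}

    def side(tag: str) -> str:
        """Build one parental side; returns the parent's id."""
        ggm = sim.add_founder(f"{tag}_ggm")
        ggf = sim.add_founder(f"{tag}_ggf")
        gm = sim.add_child(f"{tag}_gm", ggm, ggf)
        gf = sim.add_founder(f"{tag}_gf")
        if spec.include_grandparents:
            rel[gm] = rel[gf] = "grandparent"
        parent = sim.add_child(f"{tag}_parent", gm, gf)
        for a in range(spec.n_aunts_per_side):
            aunt = sim.add_child(f"{tag}_aunt{a}", gm, gf)
            rel[aunt] = "aunt_uncle"
            spouse = sim.add_founder(f"{tag}_aunt{a}_sp")
            for c in range(spec.n_cousins_per_aunt):
                rel[sim.add_child(f"{tag}_cousin{a}_{c}", aunt, spouse)] = "first_cousin"
        if spec.n_second_per_side:
            gu = sim.add_child(f"{tag}_greatuncle", ggm, ggf)
            gusp = sim.add_founder(f"{tag}_gu_sp")
            pc = sim.add_child(f"{tag}_parent_cousin", gu, gusp)
            pcsp = sim.add_founder(f"{tag}_pc_sp")
            for s in range(spec.n_second_per_side):
                rel[sim.add_child(f"{tag}_second{s}", pc, pcsp)] = "second_cousin"
        return parent

    mother = side("m")
    father = side("p")
    proband = sim.add_child("proband", mother, father)
    if spec.include_sibling or spec.include_nephew:
        sib = sim.add_child("sibling", mother, father)
        if spec.include_sibling:
            rel[sib] = "full_sibling"
        if spec.include_nephew:
            sp = sim.add_founder("sib_sp")
            rel[sim.add_child("nephew", sib, sp)] = "nephew"
    if spec.include_twin:
        rel[sim.add_twin("twin", proband)] = "identical_twin"
    for u in range(spec.n_unrelated):
        rel[sim.add_founder(f"unrel{u}")] = "unrelated"

    db_ids = sorted(rel)
    g = sim.genotypes([proband] + db_ids)
    return SimDatabase(g, sim.truth, sim, proband, "m_parent", "p_parent",
                       db_ids, rel)


# ---------------------------------------------------------------------------
# truth queries

def true_ibd_segments(truth: SimTruth, a: str, b: str,
                      min_cm: float = 8.0) -> list[IBDSegment]:
    """Maximal intervals where a and b inherit the same founder haplotype
    on at least one haplotype each, at least ``min_cm`` long."""
    ta, tb = truth.tracks[a], truth.tracks[b]
    share = np.zeros(truth.sites.n_sites, bool)
    for i in range(2):
        for j in range(2):
            share |= ta[i] == tb[j]
    out: list[IBDSegment] = []
    cm = truth.sites.cm
    for chrom, sl in truth.sites.chrom_slices().items():
        s = share[sl]
        edges = np.flatnonzero(np.diff(np.concatenate(([0], s.view(np.int8), [0]))))
        for k in range(0, len(edges), 2):
            lo, hi = edges[k] + sl.start, edges[k + 1] - 1 + sl.start
            length = float(cm[hi] - cm[lo])
            if length >= min_cm:
                out.append(IBDSegment(b, chrom, lo, hi + 1, length, length))
    return out


def true_parent_side(truth: SimTruth, proband: str, other: str,
                     start: int, end: int) -> int:
    """Which proband haplotype (0 = maternal, 1 = paternal) is shared with
    ``other`` over [start, end); -1 if neither.  Majority by site count."""
    tp = truth.tracks[proband][:, start:end]
    to = truth.tracks[other][:, start:end]
    counts = [int(((tp[h] == to[0]) | (tp[h] == to[1])).sum()) for h in (0, 1)]
    if counts[0] == counts[1] == 0:
        return -1
    return int(np.argmax(counts))


# ---------------------------------------------------------------------------
# perturbation and trivial pre-phase

def perturb_genotypes(g: GenotypeMatrix, missing_rate: float = 0.01,
                      error_rate: float = 0.002, seed: int = 0,
                      individuals: list[str] | None = None
                      ) -> tuple[GenotypeMatrix, list[tuple[str, int, int, int, str]]]:
    """Plant missingness and het<->hom genotype errors.

    Sites are selected uniformly and independently; a call selected for
    both becomes missing (missing-first).  Errors flip heterozygotes to a
    random homozygote and homozygotes to heterozygous.  Returns the
    perturbed matrix and a log of (individual, site, old, new, kind).
    """
    if not (0 <= missing_rate <= 1 and 0 <= error_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = g.calls.copy()
    log: list[tuple[str, int, int, int, str]] = []
    targets = individuals if individuals is not None else g.samples
    for ind in targets:
        i = g.samples.index(ind)
        row = calls[i]
        u = rng.random(len(row))
        miss = u < missing_rate
        err = (u >= missing_rate) & (u < missing_rate + error_rate) & (row != MISSING)
        for j in np.flatnonzero(miss & (row != MISSING)):
            log.append((ind, int(j), int(row[j]), MISSING, "missing"))
        row[miss] = MISSING
        for j in np.flatnonzero(err):
            old = int(row[j])
            new = int(rng.choice([0, 2])) if old == 1 else 1
            row[j] = new
            log.append((ind, int(j), old, new, "error"))
    return GenotypeMatrix(g.sites, list(g.samples), calls), log


def naive_prephase(g: GenotypeMatrix, individual: str) -> PrePhase:
    """Trivial frequency-based default phase.

    Heterozygotes are oriented arbitrarily (ref allele on hapA), missing
    calls are imputed to the most likely Hardy-Weinberg genotype at the
    database allele frequency.  Long-range phase is therefore no better
    than chance — exactly the role the default phase plays.
    """
    row = g.row(individual).copy()
    present = g.calls != MISSING
    with np.errstate(invalid="ignore"):
        f = np.where(present, g.calls, 0).sum(axis=0) / (2.0 * np.maximum(present.sum(axis=0), 1))
    imputed = row == MISSING
    probs = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
    row[imputed] = np.argmax(probs[:, imputed], axis=0).astype(np.int8)
    hapA = np.where(row == 1, 0, row // 2).astype(np.int8)
    hapB = np.where(row == 1, 1, row // 2).astype(np.int8)
    return PrePhase(hapA, hapB, imputed)
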