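"""Genotype, genetic-map and segment I/O.

All components share a single SNP panel: an ordered list of biallelic
autosomal sites with a genetic-map (centimorgan) coordinate per site.
Internally every interval is a 0-based half-open range of panel site
indices; 1-based physical positions appear only at file boundaries.

Interchange formats: VCF 4.2 for genotypes and phased output, a
whitespace-delimited ``chrom pos cM`` text file (PLINK-map-like) for the
genetic map, and TSV for IBD segment tables.  A packed-bitplane binary
store (:class:`BitsetStore`) is provided for fast per-individual access.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ibdphase")

#: sentinel for a missing diploid call / haploid allele
MISSING: int = -1


class PanelError(ValueError):
    """Raised when an input cannot be reconciled with the SNP panel."""


@dataclass
class SiteIndex:
    """The shared SNP panel: per-site chromosome, position and cM coordinate.

    Sites are sorted by (chromosome order of first appearance, position);
    ``idx`` is implicit as the array position.  ``cm`` must be
    non-decreasing within each chromosome.
    """

    chrom: np.ndarray          # object/str array, length n_sites
    pos: np.ndarray            # int64, 1-based physical positions
    cm: np.ndarray             # float64, genetic positions

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if not (len(self.chrom) == len(self.pos) == len(self.cm)):
            raise PanelError("chrom/pos/cm length mismatch")
        for c, sl in self.chrom_slices().items():
            d = np.diff(self.cm[sl])
            if len(d) and d.min() < 0:
                raise PanelError(f"cM not monotone on chromosome {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def chroms(self) -> list[str]:
        """Chromosome labels in panel order."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def chrom_slices(self) -> dict[str, slice]:
        """Map chromosome label -> slice of global site indices."""
        out: dict[str, slice] = {}
        start = 0
        labels = self.chrom
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                out[labels[start]] = slice(start, i)
                start = i
        return out

    def genome_cm(self) -> float:
        """Total genetic length (sum of per-chromosome cM spans)."""
        total = 0.0
        for sl in self.chrom_slices().values():
            total += float(self.cm[sl.stop - 1] - self.cm[sl.start])
        return total

    def lookup(self) -> dict[tuple[str, int], int]:
        """(chrom, pos) -> global idx dictionary."""
        return {(c, int(p)): i for i, (c, p) in enumerate(zip(self.chrom, self.pos))}


@dataclass
class GenotypeMatrix:
    """Diploid calls (alt-allele counts 0/1/2, MISSING=-1) on the shared panel."""

    sites: SiteIndex
    samples: list[str]
    calls: np.ndarray  # int8, shape (n_samples, n_sites)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), self.sites.n_sites):
            raise PanelError("calls shape inconsistent with samples x sites")
        if len(set(self.samples)) != len(self.samples):
            raise PanelError("duplicated individual ID")
        self._index = {s: i for i, s in enumerate(self.samples)}

    def row(self, individual: str) -> np.ndarray:
        try:
            return self.calls[self._index[individual]]
        except KeyError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def __contains__(self, individual: str) -> bool:
        return individual in self._index


@dataclass
class PrePhase:
    """An externally phased (or trivially defaulted) proband haplotype pair.

    ``hapA + hapB`` must reproduce the raw diploid call at every site where
    the raw call is non-missing; ``imputed_mask`` marks sites that were
    missing in the raw genotype and imputed here.
    """

    hapA: np.ndarray           # int8 in {0,1,MISSING}
    hapB: np.ndarray
    imputed_mask: np.ndarray   # bool

    def genotype(self) -> np.ndarray:
        """Diploid calls implied by the haplotypes (MISSING where either is)."""
        g = self.hapA.astype(np.int8) + self.hapB.astype(np.int8)
        g[(self.hapA == MISSING) | (self.hapB == MISSING)] = MISSING
        return g


# ---------------------------------------------------------------------------
# genetic map

def read_genetic_map(path: str | Path, panel_chrom: np.ndarray,
                     panel_pos: np.ndarray) -> np.ndarray:
    """Interpolate cM coordinates for panel sites from a map file.

    The file holds whitespace-delimited ``chrom pos cM`` rows with cM
    monotone non-decreasing within each chromosome.  Panel sites between
    map rows get linearly interpolated cM; sites outside the mapped range
    are clamped to the nearest endpoint's cM.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "pos", "cm"],
                     dtype={"chrom": str, "pos": np.int64, "cm": np.float64})
    cm_out = np.empty(len(panel_pos), dtype=np.float64)
    panel_chrom = np.asarray(panel_chrom, dtype=object)
    for c in pd.unique(df["chrom"]):
        sub = df[df["chrom"] == c]
        if (np.diff(sub["cm"].to_numpy()) < 0).any():
            raise PanelError(f"non-monotone cM in map for chromosome {c}")
    for c in np.unique(panel_chrom.astype(str)):
        sub = df[df["chrom"] == c]
        mask = panel_chrom == c
        if not len(sub):
            raise PanelError(f"chromosome {c} absent from genetic map")
        # np.interp clamps outside the range, matching the endpoint rule
        cm_out[mask] = np.interp(panel_pos[mask].astype(float),
                                 sub["pos"].to_numpy(dtype=float),
                                 sub["cm"].to_numpy())
    return cm_out


def write_genetic_map(sites: SiteIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, p, m in zip(sites.chrom, sites.pos, sites.cm):
            fh.write(f"{c}\t{p}\t{m:.6f}\n")


# ---------------------------------------------------------------------------
# VCF

def _parse_gt(gt: str) -> int:
    a = gt.replace("|", "/").split("/")
    if "." in a or len(a) != 2:
        return MISSING
    return int(a[0]) + int(a[1])


def read_vcf(path: str | Path, panel: SiteIndex | None = None) -> GenotypeMatrix:
    """Read unphased diploid genotypes from a VCF, aligned to ``panel``.

    If ``panel`` is None the panel is taken from the file itself (cM all
    zero until a map is attached).  Sites absent from the panel are dropped
    with a warning; panel sites absent from the file are MISSING.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise PanelError("duplicated individual ID in VCF")
    chroms, poss, rows = [], [], []
    for var in vcf:
        # gts012: 0/1/2 = alt count, 3 = unknown
        g = var.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(g)
    vcf.close()
    calls_by_site = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), np.int8)
    if panel is None:
        panel = SiteIndex(np.array(chroms, dtype=object),
                          np.array(poss, dtype=np.int64),
                          np.zeros(len(poss)))
        calls = calls_by_site.T.copy()
        return GenotypeMatrix(panel, samples, calls)
    look = panel.lookup()
    calls = np.full((len(samples), panel.n_sites), MISSING, dtype=np.int8)
    dropped = 0
    for (c, p, g) in zip(chroms, poss, calls_by_site):
        j = look.get((c, int(p)))
        if j is None:
            dropped += 1
            continue
        calls[:, j] = g
    if dropped:
        warnings.warn(f"{dropped} VCF sites absent from panel were dropped")
    return GenotypeMatrix(panel, samples, calls)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ibdphase
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _gt_string(a: int, b: int, phased: bool) -> str:
    sa = "." if a == MISSING else str(int(a))
    sb = "." if b == MISSING else str(int(b))
    return f"{sa}{'|' if phased else '/'}{sb}"


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write unphased diploid calls as VCF 4.2 (REF=A, ALT=C placeholders)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for j in range(g.sites.n_sites):
            gts = []
            for i in range(len(g.samples)):
                c = g.calls[i, j]
                if c == MISSING:
                    gts.append("./.")
                elif c == 0:
                    gts.append("0/0")
                elif c == 1:
                    gts.append("0/1")
                else:
                    gts.append("1/1")
            fh.write(f"{g.sites.chrom[j]}\t{g.sites.pos[j]}\t.\tA\tC\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def write_phased_vcf(hapA: np.ndarray, hapB: np.ndarray, sites: SiteIndex,
                     path: str | Path, sample: str = "proband",
                     corrections: list | None = None) -> None:
    """Write a phased haplotype pair as single-sample VCF (``a|b`` GT).

    A corrections sidecar TSV (``<path>.corrections.tsv``) is emitted when
    a corrections log is given: site index, chrom, pos, original call,
    emitted call, and evidence class.
    """
    if len(hapA) != sites.n_sites or len(hapB) != sites.n_sites:
        raise PanelError("haplotype length mismatch with panel")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for j in range(sites.n_sites):
            fh.write(f"{sites.chrom[j]}\t{sites.pos[j]}\t.\tA\tC\t.\tPASS\t.\tGT\t"
                     + _gt_string(hapA[j], hapB[j], phased=True) + "\n")
    if corrections is not None:
        with open(str(path) + ".corrections.tsv", "w") as fh:
            fh.write("idx\tchrom\tpos\toriginal\temitted\tkind\n")
            for (j, orig, new, kind) in corrections:
                fh.write(f"{j}\t{sites.chrom[j]}\t{sites.pos[j]}\t{orig}\t{new}\t{kind}\n")


def read_phased_vcf(path: str | Path, panel: SiteIndex | None = None
                    ) -> tuple[np.ndarray, np.ndarray, SiteIndex]:
    """Read a single-sample phased VCF back into (hapA, hapB, panel)."""
    chroms, poss, ha, hb = [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise PanelError(f"malformed VCF line {ln}")
            gt = f[9].split(":")[0]
            alleles = gt.split("|") if "|" in gt else gt.split("/")
            if len(alleles) != 2:
                raise PanelError(f"non-diploid GT at line {ln}")
            chroms.append(f[0])
            poss.append(int(f[1]))
            ha.append(MISSING if alleles[0] == "." else int(alleles[0]))
            hb.append(MISSING if alleles[1] == "." else int(alleles[1]))
    if panel is None:
        panel = SiteIndex(np.array(chroms, dtype=object),
                          np.array(poss, dtype=np.int64), np.zeros(len(poss)))
        return np.array(ha, np.int8), np.array(hb, np.int8), panel
    look = panel.lookup()
    A = np.full(panel.n_sites, MISSING, np.int8)
    B = np.full(panel.n_sites, MISSING, np.int8)
    for c, p, a, b in zip(chroms, poss, ha, hb):
        j = look.get((c, p))
        if j is not None:
            A[j], B[j] = a, b
    return A, B, panel


# ---------------------------------------------------------------------------
# IBD segment tables

SEGMENT_COLUMNS = ["proband_id", "other_id", "chrom", "start_idx", "end_idx", "cm_length"]


def write_segments_tsv(segments, proband_id: str, sites: SiteIndex,
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for s in segments:
            fh.write(f"{proband_id}\t{s.other_id}\t{s.chrom}\t{s.start}\t{s.end}\t"
                     f"{s.cm_length:.4f}\n")


def read_segments_tsv(path: str | Path):
    from .ibd import IBDSegment
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for r in df.itertuples(index=False):
        out.append(IBDSegment(other_id=str(r.other_id), chrom=str(r.chrom),
                              start=int(r.start_idx), end=int(r.end_idx),
                              cm_length=float(r.cm_length),
                              trimmed_cm=float(r.cm_length)))
    return out


# ---------------------------------------------------------------------------
# packed-bitplane binary store

class BitsetStore:
    """Per-individual packed homozygosity bitplanes on disk.

    Layout: a JSON header line (panel size, sample order) followed by, per
    individual, three bit-packed planes (hom-ref, hom-alt, missing), each
    ``ceil(n_sites / 8)`` bytes, big-endian bit order as produced by
    ``np.packbits``.  Heterozygous = none of the three planes set.  The
    store is indexed by individual so a single genome can be read without
    touching the rest of the file.
    """

    MAGIC = b"IBDPBIT1"

    @classmethod
    def write(cls, g: GenotypeMatrix, path: str | Path) -> None:
        nb = (g.sites.n_sites + 7) // 8
        header = json.dumps({"n_sites": g.sites.n_sites,
                             "samples": g.samples}).encode()
        with open(path, "wb") as fh:
            fh.write(cls.MAGIC)
            fh.write(len(header).to_bytes(8, "little"))
            fh.write(header)
            for i in range(len(g.samples)):
                row = g.calls[i]
                for plane in (row == 0, row == 2, row == MISSING):
                    fh.write(np.packbits(plane).tobytes().ljust(nb, b"\0"))

    def __init__(self, path: str | Path):
        self._fh = open(path, "rb")
        if self._fh.read(8) != self.MAGIC:
            raise PanelError("not a bitset store")
        hlen = int.from_bytes(self._fh.read(8), "little")
        hdr = json.loads(self._fh.read(hlen))
        self.n_sites = hdr["n_sites"]
        self.samples = hdr["samples"]
        self._nb = (self.n_sites + 7) // 8
        self._base = 16 + hlen
        self._index = {s: i for i, s in enumerate(self.samples)}

    def planes(self, individual: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Packed (hom_ref, hom_alt, missing) uint8 planes for one individual."""
        i = self._index[individual]
        self._fh.seek(self._base + i * 3 * self._nb)
        buf = np.frombuffer(self._fh.read(3 * self._nb), dtype=np.uint8)
        return buf[:self._nb], buf[self._nb:2 * self._nb], buf[2 * self._nb:]

    def genotypes(self, individual: str) -> np.ndarray:
        hr, ha, mi = (np.unpackbits(p)[: self.n_sites].astype(bool)
                      for p in self.planes(individual))
        g = np.ones(self.n_sites, np.int8)  # het unless a plane says otherwise
        g[hr] = 0
        g[ha] = 2
        g[mi] = MISSING
        return g

    def close(self) -> None:
        self._fh.close()
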