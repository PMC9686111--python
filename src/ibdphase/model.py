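"""Top-level modelling interface.

`IBDPhaseModel` holds a proband, a genotype database and the pipeline
configuration; `fit()` runs IBD detection, close-family screening, the
parental-group scan, sub/supercluster phasing and genome-wide phase
emission, returning a `PhaseResults` with the phased haplotypes, cluster
labels, diagnostics and a `summary()` table.

    >>> db = make_database(SimConfig(n_chrom=4, chrom_cm=60, spacing_cm=0.05))
    >>> res = IBDPhaseModel(db.genotypes, db.proband).fit(seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (MISSING, GenotypeMatrix, PrePhase, SiteIndex, read_vcf,
                 read_genetic_map, write_phased_vcf)
from .ibd import DetectConfig, IBDSegment, RelationshipStats, detect_all, \
    detect_ibd2_runs, relationship_stats
from .family import (CloseFamilyGraph, build_family_graph, discard_unreliable,
                     select_close_relatives)
from .split import GroupAssignment, SplitConfig, assign_parental_groups
from .cluster import (ClusterConfig, ConnectionGraph, Subcluster, Supercluster,
                      build_connection_graph, build_subclusters,
                      fragment_global_sides, largest_supercluster,
                      phase_superclusters, prune_supercluster)
from .phaser import (PROV_BOTH_SIDES, PROV_ONE_SIDE, PROV_PREPHASE,
                     PhaseConfig, PhasedGenome, phase_genome)
from .confidence import ConfidenceFeatures, extract_features
from .metrics import (TrioTruth, global_phase_error, pct_snps_in_1cm_runs,
                      segment_assignment_error, switch_error_rate)
from .sim import SimTruth, naive_prephase, true_parent_side


class IBDPhaseModel:
    """Genome-wide phasing of one proband from a genotype database.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Proband and database individuals on the shared SNP panel.
    proband : str
        Individual to phase.
    prephase : PrePhase, optional
        Locally phased default; a trivial frequency-based default is built
        when absent.
    segments : list of IBDSegment, optional
        Precomputed IBD segments; detected from the genotypes when absent.
    exclude : iterable of str
        Individuals never used as IBD donors (e.g. the proband's parents
        in an evaluation run).
    detect_site_mask : bool array, optional
        Restrict IBD detection to these panel sites (held-out-SNP
        perturbation experiments).
    """

    def __init__(self, genotypes: GenotypeMatrix, proband: str,
                 prephase: PrePhase | None = None,
                 segments: list[IBDSegment] | None = None,
                 exclude: tuple = (),
                 detect: DetectConfig | None = None,
                 split: SplitConfig | None = None,
                 cluster: ClusterConfig | None = None,
                 phase: PhaseConfig | None = None,
                 detect_site_mask: np.ndarray | None = None):
        if proband not in genotypes:
            raise KeyError(f"proband {proband!r} not in genotype matrix")
        self.genotypes = genotypes
        self.proband = proband
        self.prephase = prephase
        self.segments = segments
        self.exclude = set(exclude)
        self.detect_cfg = detect or DetectConfig()
        self.split_cfg = split or SplitConfig()
        self.cluster_cfg = cluster or ClusterConfig()
        self.phase_cfg = phase or PhaseConfig()
        self.detect_site_mask = detect_site_mask

    @classmethod
    def from_vcf(cls, vcf_path, map_path, proband: str,
                 prephase_vcf=None, **kw) -> "IBDPhaseModel":
        g = read_vcf(vcf_path)
        g.sites.cm[:] = read_genetic_map(map_path, g.sites.chrom, g.sites.pos)
        prephase = None
        if prephase_vcf is not None:
            from .io import read_phased_vcf
            hapA, hapB, _ = read_phased_vcf(prephase_vcf, g.sites)
            raw = g.row(proband)
            prephase = PrePhase(hapA, hapB, raw == MISSING)
        return cls(g, proband, prephase=prephase, **kw)

    def fit(self, seed: int = 0) -> "PhaseResults":
        g = self.genotypes
        proband_calls = g.row(self.proband)
        prephase = self.prephase or naive_prephase(g, self.proband)

        others = [s for s in g.samples if s != self.proband and s not in self.exclude]
        if self.segments is None:
            segments, stats = detect_all(self.proband, g, others,
                                         self.detect_cfg, self.detect_site_mask)
        else:
            segments = [s for s in self.segments if s.other_id in set(others)]
            stats = {}
            for o in sorted({s.other_id for s in segments}):
                segs_o = [s for s in segments if s.other_id == o]
                runs = detect_ibd2_runs(self.proband, o, g, self.detect_cfg)
                stats[o] = relationship_stats(self.proband, o, g, segs_o, runs)

        close = select_close_relatives(stats)
        family = build_family_graph(close, g, stats, self.detect_cfg) if close else None
        if family is not None:
            kept, discarded = discard_unreliable(family, segments)
        else:
            kept, discarded = segments, set()

        assignment = assign_parental_groups(proband_calls, kept, g, prephase,
                                            self.split_cfg)
        subclusters = build_subclusters(assignment, self.cluster_cfg)
        graph = build_connection_graph(subclusters, assignment, kept)
        superclusters = phase_superclusters(graph, subclusters, self.cluster_cfg,
                                            seed=seed)
        superclusters = [prune_supercluster(s, graph, self.cluster_cfg.min_connections)
                         for s in superclusters]
        phased = phase_genome(proband_calls, prephase, assignment, kept,
                              subclusters, superclusters, g, self.phase_cfg)
        res = PhaseResults(
            model=self, sites=g.sites, proband_calls=proband_calls,
            prephase=prephase, segments=kept, all_segments=segments,
            stats=stats, family=family, discarded=discarded,
            assignment=assignment, subclusters=subclusters, graph=graph,
            superclusters=superclusters,
            fragment_sides=fragment_global_sides(subclusters, superclusters),
            phased=phased)
        res.features = extract_features(res)
        return res


@dataclass
class PhaseResults:
    """Fitted phase for one proband: haplotypes, labels and diagnostics."""

    model: IBDPhaseModel
    sites: SiteIndex
    proband_calls: np.ndarray
    prephase: PrePhase
    segments: list[IBDSegment]
    all_segments: list[IBDSegment]
    stats: dict[str, RelationshipStats]
    family: CloseFamilyGraph | None
    discarded: set[str]
    assignment: GroupAssignment
    subclusters: list[Subcluster]
    graph: ConnectionGraph
    superclusters: list[Supercluster]
    fragment_sides: dict[int, int]
    phased: PhasedGenome
    features: ConfidenceFeatures | None = None

    @property
    def hapA(self) -> np.ndarray:
        return self.phased.hapA

    @property
    def hapB(self) -> np.ndarray:
        return self.phased.hapB

    def provenance_fractions(self) -> dict[str, float]:
        n = self.sites.n_sites
        p = self.phased.provenance
        return {"ibd_both_sides": float((p == PROV_BOTH_SIDES).sum()) / n,
                "ibd_one_side": float((p == PROV_ONE_SIDE).sum()) / n,
                "prephase_default": float((p == PROV_PREPHASE).sum()) / n}

    def to_vcf(self, path, sample: str | None = None) -> None:
        write_phased_vcf(self.hapA, self.hapB, self.sites, path,
                         sample or self.model.proband,
                         corrections=self.phased.corrections)

    # ------------------------------------------------------------------
    # evaluation against trio / simulation truth

    def evaluate(self, trio: TrioTruth) -> dict[str, float]:
        return {
            "global_phase_error": global_phase_error(
                self.hapA, self.hapB, self.proband_calls, trio),
            "switch_error_rate": switch_error_rate(
                self.hapA, self.hapB, self.proband_calls, trio),
            "pct_snps_in_1cm_runs": pct_snps_in_1cm_runs(
                self.hapA, self.hapB, self.proband_calls, trio, self.sites),
        }

    def labeled_fragments(self, truth: SimTruth) -> list[tuple[float, int, int]]:
        """(cM, assigned global side, true parental side) per fragment."""
        out = []
        for f in self.assignment.fragments:
            t = true_parent_side(truth, self.model.proband, f.other_id,
                                 f.start, f.end)
            out.append((f.cm, self.fragment_sides.get(f.id, f.side), t))
        return out

    def evaluate_segments(self, truth: SimTruth) -> float:
        return segment_assignment_error(self.labeled_fragments(truth))

    # ------------------------------------------------------------------

    def summary(self) -> str:
        big = largest_supercluster(self.superclusters, self.subclusters)
        nseg = len(self.segments)
        frac_big = 0.0
        if big is not None and nseg:
            frag_by_id = {f.id: f for f in self.assignment.fragments}
            seg_ids = {frag_by_id[fid].seg_id
                       for sc in self.subclusters if sc.id in set(big.members)
                       for fid, _ in sc.members}
            frac_big = len(seg_ids) / nseg
        prov = self.provenance_fractions()
        nA = sum(1 for s in self.fragment_sides.values() if s == 0)
        nB = len(self.fragment_sides) - nA
        corr = self.phased.corrections
        from collections import Counter
        per_seg = Counter(f.seg_id for f in self.assignment.fragments)
        n_split = sum(1 for v in per_seg.values() if v > 1)
        lines = [
            "IBD phase results",
            "=" * 58,
            f"proband                      {self.model.proband}",
            f"panel sites                  {self.sites.n_sites}",
            f"IBD individuals              {len(self.stats)}",
            f"IBD segments (kept/total)    {nseg}/{len(self.all_segments)}",
            f"discarded relatives          {len(self.discarded)}",
            f"fragments (A/B sides)        {len(self.fragment_sides)} ({nA}/{nB})",
            f"segments split (retained)    {n_split}",
            f"het sites ignored            {len(self.assignment.ignored_sites)}",
            f"subclusters                  {len(self.subclusters)}",
            f"superclusters                {len(self.superclusters)}",
            f"largest supercluster share   {frac_big:.1%} of segments",
            f"sites w/ two-sided evidence  {prov['ibd_both_sides']:.1%}",
            f"sites w/ one-sided evidence  {prov['ibd_one_side']:.1%}",
            f"sites on pre-phase default   {prov['prephase_default']:.1%}",
            f"corrections (genotype/imputed) "
            f"{sum(1 for c in corr if c[3] == 'genotype_override')}/"
            f"{sum(1 for c in corr if c[3] == 'imputed_override')}",
            "=" * 58,
        ]
        return "\n".join(lines)
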