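# Methods

This note documents the model behind `ibdphase`, the parameters that
matter, the design decisions taken where the design was genuinely open,
what the synthetic data do and do not emulate, and known limitations.

## Problem and assumptions

The goal is genome-wide separation of maternally and paternally
inherited alleles of one diploid *proband*, using identity-by-descent
(IBD) segments shared with a genotype database. The core assumptions:

* Sites are biallelic autosomal SNPs on one shared panel with a genetic
  map (cM) coordinate per site; cM is non-decreasing within a
  chromosome.
* An IBD segment means the database individual carries one haplotype
  identical to one of the proband's two. Wherever the proband is
  heterozygous and the individual homozygous, the homozygous allele must
  be the shared one — this is the only signal the split uses, so phase
  quality of the database is irrelevant and the database may be entirely
  unphased.
* An individual sharing IBD in two genomic regions more likely shares
  through one common ancestor — i.e. with the same parent of the
  proband — than through both parents independently. This is what makes
  cross-chromosome phasing possible, and it is a *statistical* tendency,
  not a guarantee; the supercluster objective aggregates many such
  connections so that occasional two-sided individuals are outvoted.

## Pipeline parameters

| parameter | default | unit | role |
|---|---|---|---|
| `DetectConfig.min_cm` | 8.0 | cM | minimum segment length; shorter IBD is increasingly identity-by-state and hurts the split |
| `DetectConfig.min_trimmed_cm` | 5.0 | cM | length after discarding inter-SNP gaps > `max_gap_cm`; rejects sparse-SNP artifacts |
| `DetectConfig.max_gap_cm` | 0.05 | cM | gap size above which a gap contributes nothing to trimmed length |
| `DetectConfig.min_ibd2_cm` | 5.0 | cM | minimum IBD2 (identical-genotype) run length |
| close-family threshold | 400 | cM | total sharing defining "close family" |
| twin rule | 0.90 | — | IBD2-run genome fraction identifying an identical twin |
| sibling rule | 1300 / 0.09 / 0.99 | cM / — / — | total sharing, IBD2-run fraction, IBD1-rate cap identifying a full sibling |
| `EndpointWeighting.d0`, `.slope` | 1.0, 4.0 | cM, /cM | sigmoid down-weighting of votes near segment ends |
| `SplitConfig.switch_trigger` | 1.0 | weighted segments | forced-switch mass that triggers the lookahead |
| `SplitConfig.lookahead_window` | 20 | het sites | flank examined on each side |
| `SplitConfig.lookahead_cost` | 1.0 | weighted segments | contradiction cost above which a site is ignored |
| `SplitConfig.min_fragment_cm` | 5.0 | cM | retention threshold for broken-segment pieces (longest piece always kept; pieces separated by one SNP merged) |
| `ClusterConfig.min_weighted_overlap` | 10.0 | weighted sites | informative overlap required inside a subcluster |
| `ClusterConfig.restarts` | 1000 | — | random restarts of the greedy orientation search |
| `ClusterConfig.min_connections` | 3 | connections | supercluster pruning for confident labeling |
| `PhaseConfig.genotype_override` | 1.0 | weighted segments | evidence needed to override a non-missing call |
| `PhaseConfig.impute_override` | 0.1 | weighted segments | evidence needed to override an imputed call or orient a heterozygote |

The endpoint weight is $w(d) = 1/(1+e^{-\text{slope}(d-d_0)})$ of the cM
distance $d$ to the nearer segment end: ~0.02 at the endpoint, 0.5 at
$d_0 = 1$ cM, >0.999 beyond 4 cM. Unphased opposite-homozygote detection
systematically overshoots true segment ends (it keeps running until the
first conflict), and the ~1 cM scale matches that overshoot for 8 cM+
segments on dense panels, so votes from the unreliable fringe are
discounted without discarding them.

## Numerical and procedural choices

* **Coordinates.** All intervals are 0-based half-open panel-index
  ranges; physical 1-based positions exist only at file boundaries.
  Segment genetic length is measured from the first to the last site of
  the run (closed on site cM values).
* **Missing data.** Missing calls never conflict, so they never break an
  IBD segment; inside IBD2 runs they neither break nor extend a run (a
  run is delimited by sites where both calls are present and equal).
* **Scan tie-breaks.** When both orientations of a heterozygous site
  score equally (including the no-evidence case), the pre-phase
  orientation is followed, carried as a parity bit (pre-phase hapA on
  side A, or flipped) from the previous heterozygous site. Before any
  segment is assigned on a chromosome, the first informative site's
  partition defines the sides.
* **Lookahead arithmetic.** Which quantity to compare against the 1.0
  ignore cost is open; here, for each segment the trigger site would
  flip, the 20 flanking heterozygous sites on each side vote on its side
  by pairwise allele agreement with currently-assigned segments
  (same homozygous allele = same side), weighted by the product of
  endpoint weights. If the flanks contradict flips worth more than 1.0
  weighted segments at the trigger site, the site is ignored. Only
  homozygous genotypes in overlapping segments are consulted, which is
  why a window of sites, not one site, is needed.
* **Subcluster overlap weight.** A shared informative site contributes
  the product of the two fragments' endpoint weights.
* **Greedy search determinism.** Restart $r$ of component $c$ draws its
  initial orientation from substream $(seed, c, r)$; among equal-gain
  flips the lowest subcluster id wins, making runs bit-reproducible and
  order-independent.
* **Orientation frames.** Each supercluster fixes its own A/B frame;
  frames of different superclusters are mutually arbitrary (nothing
  connects them, so no assignment could be better than arbitrary). For
  sites that fall back to the pre-phase, the scan's chromosome-local
  parity is mapped into the global frame through the orientation bit of
  the chromosome's dominant (largest fragment-cM) subcluster.
* **Override conflicts.** If fragments on the *same* side are homozygous
  for different alleles, the majority weight wins, ties fall back to the
  original call, and the site is logged as a conflict. Heterozygote
  orientation requires ≥ 0.1 weighted evidence; genotype *changes*
  require ≥ 1.0 on every contributing side (0.1 when the original call
  was missing), and one-sided evidence may only override homozygous
  calls. Sites emitted from the pre-phase always reproduce the original
  diploid call.
* **Degenerate inputs.** No segments → the output equals the pre-phase
  at every site; no comparable sites between a pair, an empty
  trio-resolvable mask, or fewer than two resolvable heterozygotes are
  errors, not silent zeros; degenerate confidence ratios (empty
  denominators) are emitted as a documented cap (100).
* **Metric conventions.** Global phase error takes the better of the two
  haplotype↔parent mappings; missing emitted alleles at resolvable sites
  count as errors there (conservative) but are excluded from switch
  error. Switch-free runs do not cross chromosome boundaries. Segment
  assignment error is cM-weighted by default (count-weighting is a
  flag) over retained fragments, under a single genome-wide
  side↔parent mapping.

## What the simulator emulates

Founder haplotypes are site-independent draws from an allele-frequency
spectrum (default Uniform(0.05, 0.5)); each meiosis places
Poisson($L/100$) crossovers uniformly in cM per chromosome (no
interference); genotypes are unphased allele counts; perturbation plants
1% missingness and 0.2% het↔hom call errors, selected uniformly,
missing-first. Transmission tracks record the founder haplotype of every
position, so true IBD and the true parental side of any shared fragment
are exact. The database builder assembles a proband with one-sided
relatives per side (grandparents, aunts/uncles, first and second
cousins), optional two-sided relatives (identical twin, full sibling,
nephew) and unrelated individuals.

Deliberately *not* emulated: linkage disequilibrium and realistic
haplotype sharing between "unrelated" individuals (founders share
nothing, so there is no identity-by-state background and no two-sided
noise from founder effects), population structure, array genotyping
artifacts beyond uniform random errors, and sex chromosomes. Passing
tests therefore demonstrate correctness of the machinery and its
robustness to random noise at the stated rates — not performance on a
real biobank, where short spurious IBD and parents with shared ancestry
make the supercluster problem strictly harder.

## Problem sizes used in tests and the acceptance script

Chosen once as desk-scale study conditions: the default simulated genome
is 10 autosomes × 100 cM at 0.02 cM SNP spacing (50,010 sites,
dense-array-like). End-to-end replicates use that map with a
63-individual database (per side: 2 grandparents, 4 aunts/uncles, 12
first cousins, 6 second cousins; plus 15 unrelated), giving roughly
5–7× IBD coverage per parental side — 20 replicates in the test suite,
10 in the acceptance script. The perturbation experiment uses the same
database over 6 × 100 cM, detects IBD on a uniformly chosen 63% of SNPs
and scores imputation/correction on the held-out 37%, since planted
errors would otherwise alter detection at the very sites being scored.
Relative-filter families use a stylized 18 × 190 cM autosome (~3,420 cM
total): the twin/sibling/close-family rules are absolute cM thresholds
and presume a human-scale autosomal map. Confidence-model checks use
synthetic feature tables (planted-signal and permuted-label nulls) plus
24 small pipeline runs spanning sparse-to-dense coverage for the
predicted-vs-observed correlation.

## Known limitations

* Subclusters on the same chromosome that never join a common
  supercluster keep mutually arbitrary orientations; pre-phase carryover
  across the gap is the only tie, and it is as good as the pre-phase.
* The descendant-of-both-parents test is structural (adjacency to all
  other close family) and is vacuous with fewer than two other close
  relatives; such individuals are kept.
* Heterozygous proband calls contradicted by strong two-sided evidence
  for a homozygote are overridden and logged; with genuinely erroneous
  database genotypes this can introduce (rare, logged) miscorrections.
* The greedy orientation search is exact only empirically (checked
  against exhaustive enumeration on small graphs); no optimality
  guarantee exists for large components.
* Founders are simulated without a coalescent model; IBD-detection
  false-positive behavior on real data is therefore understated.
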