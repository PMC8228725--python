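# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the design
decisions taken where the procedure was genuinely open.

## Candidate filtering

A candidate record mirrors one row of a hairpin-predictor result table:
likelihood score, predicted precursor/mature/star/loop sequences, per-arm
read counts, and a precomputed homology flag (whether the precursor matched a
known miRNA precursor in a reference set; running the homology search itself
is out of scope). Acceptance requires

1. score ≥ `score_min` (default 1.0, inclusive),
2. both a star and a loop sequence present, and
3. homology **or** expression evidence (mature reads ≥ `min_mature_reads`,
   default 30) — the two are alternatives, which is why star-dominant
   records (star reads > mature reads) can legitimately stay in the set when
   both arms clear the cutoff; the flag is informational only.

Rejection reasons are assigned in the fixed order score → structure →
evidence, so reports are deterministic. The read cutoff is applied to counts
summed across libraries (configurable). The cascade is monotone: raising
either threshold can only shrink the accepted set, and the accepted/rejected
lists partition the input.

## Locus annotation

Localization is exact, full-length string matching of each precursor against
both strands of every chromosome (U/T-insensitive; `N` never matches). Since
only hits with complete query coverage and zero mismatches count, exact
matching is equivalent to an alignment step followed by that filter, and it
is deterministic. Every distinct (chromosome, start, strand) occurrence is
reported; a precursor placed twice yields two loci.

Families are keyed on the exact mature sequence; family ids are assigned by
lexicographic order of the mature string so numbering is input-order
independent. Novel loci are named `api-mir-x<N>` with `N` running over novel
families in family-id order; families with several loci get letter suffixes
(`a`, `b`, ...) in (chromosome, start) order. The numbering restarts at 1
per run — the mapping from families to x-numbers is a per-run convention —
and a generated name colliding with a supplied known name is an error.

Clusters chain loci per chromosome after sorting by start: an adjacent pair
chains when `next.start − prev.end < max_gap_bp` (default 10,000), where
`prev.end` is the running maximum end of the chain so nested or overlapping
loci chain as expected. Maximal chains of ≥ 2 loci are clusters; strand is
ignored; the gap metric is end-to-start distance, the intuitive notion of
"separated by". This chaining provably equals the transitive closure of the
pairwise "intervals less than 10 kb apart" relation, and the test suite
checks that equality against an independent union-find oracle on random
instances. A cluster is single-family iff all members share one family id
(paralogous copies), else multifamily.

The distribution summary mirrors the published table layout: one row per
chromosome plus a pooled unplaced-scaffold row, with novel/known/total/
male-biased locus counts, genome proportion (chromosome size over total
size) and a grand-total row. Internal coordinates are 0-based half-open;
GFF3 output is 1-based inclusive (`miRNA_primary_transcript` features) and
cluster spans are written as BED4.

## Expression quantification and sex bias

Read processing: optional adapter clip at the leftmost adapter occurrence,
truncation at the first base (5′→3′) with Phred quality below 20, then a
length filter to [18, 35] nt. Counting assigns each processed read to the
first precursor (sorted-id order) containing it as an exact substring;
the deterministic tie-break stands in for an aligner's arbitrary choice on
multi-mapping reads and means copies of one mature sequence accumulate on
the lexicographically first family member. A Hamming-distance scan is
available (`max_mismatches > 0`) but the default is exact for determinism.
Unmatched reads are tallied per sample. CPM = count / matched library total
× 10⁶; an all-zero sample yields zeros with a warning rather than NaNs.

Bias rule: with one male library and many female libraries, a miRNA is
male-biased at level k when `male_cpm ≥ k · max_female_cpm` **and**
`male_cpm ≥ expression_floor` (default 1 CPM). The comparison is inclusive
("five times higher" read as ratio ≥ 5). The floor handles miRNAs absent
from all female libraries, where the ratio would otherwise be infinite; the
reported ratio uses `max(max_female_cpm, floor)` as denominator. With
several male samples the maximum male CPM is used. The k = 5 set is a
subset of the k = 2 set by construction.

Statistics: Pearson χ² goodness of fit (against genome-proportion
expectations) and r×c contingency tests are computed from the direct
formulas, no continuity correction by default (Yates optional). The
X-vs-autosome comparison summarizes each placed miRNA as its mean
log10(CPM + 1) across samples and applies a two-sided Mann–Whitney rank-sum
test — a signed-rank test would require paired observations, which an
X-vs-autosome split does not provide — using exact enumeration when both
groups have ≤ 20 untied values and the normal approximation with tie
correction otherwise; two identical groups give p = 1.

## Target prediction

A site is anchored by the seed: miRNA positions 2–8 must pair with the UTR
by perfect Watson–Crick complementarity (no G:U, no mismatch). Pairing may
extend beyond the 7-mer toward the miRNA 3′ end; because miRNA and site are
antiparallel the extension grows the UTR window 5′-ward. The scanner
reports, for every offset at which some window of length ≥ 7 is the exact
reverse complement of the miRNA window starting at position 2, the maximal
such length; it is tested against an exhaustive offset × length scan.

Duplex energy is the sum of base-pair stacking terms over the perfectly
paired region, looked up by the miRNA-side dinucleotide; a single pair
contributes 0. The packaged 16-entry table approximates Watson–Crick RNA
nearest-neighbor stack free energies (kcal/mol) and is fully replaceable.
One engine run under three profiles replaces three external predictors: the
reproducible content of that practice is the decision rule (seed constraints
+ an energy threshold + optionally a p-value), not the tools' internal
energy models. Thresholds: 0, 0 and −15 kcal/mol, compared inclusively
(≤). The second profile adds an empirical p: the fraction (with add-one
correction) of 1000 dinucleotide-shuffled versions of the UTR whose best
site energy is at least as low as the observed site's, retained iff
p < 0.05; the shuffle is a seeded Eulerian-walk construction, and this
permutation p is documented as *not* equivalent to any external tool's
analytic model. The final interaction list is the pair-level intersection:
a (miRNA, gene) pair is kept only if that exact pair is predicted under
every profile — gene-level overlap with a different miRNA partner does not
count. Site coordinates are not required to agree across profiles.

## Differential expression and overlap

The DE stage is a deliberately minimal NB pipeline, documented as
simplified and not equivalent to a full shrinkage-based package (a
precomputed DE table can be supplied to reproduce that stage boundary):

- size factors: median-of-ratios over genes with all-positive counts
  (library-size ratios as fallback);
- per-gene dispersion α in `var = μ + αμ²` by pooled method of moments,
  floored at 10⁻⁸ (α = 0 degenerates to Poisson);
- Wald test on the log2 ratio of normalized group means (pseudocount 0.5),
  delta-method standard error;
- two-sided p from a **t reference with n₁ + n₂ − 2 df**. With three
  replicates per group the plug-in variance makes a standard-normal
  reference anticonservative (measured null p < 0.05 fraction ≈ 0.11); the
  t reference brings it to ≈ 0.04, slightly conservative, which is the
  behavior we ship;
- BH adjustment over all tested genes; genes with zero counts everywhere
  are excluded from testing and from the adjustment. Which genes count as
  "expressed" is this inclusion rule and is configurable — published
  expressed-gene totals depend on unstated filtering and are not
  reproducible quantities.

Significance: padj < 0.05 and linear fold change strictly > 4,
direction-agnostic before splitting into higher-in-male / higher-in-female.
The overlap stage restricts intersected target pairs to miRNAs in the
male-biased set, intersects the targeted genes with the male-down genes, and
reports Venn counts (targets only / DE-down only / both) plus the targeting
miRNAs per overlap gene.

## Synthetic data: what it emulates, and what it does not

The generator emulates the study design at desk scale: four chromosomes
(A1, A2, A3, X) plus an unplaced scaffold with sizes roughly proportional
to the real assembly (≈ 1 Mb total); 60 miRNA loci, 6 of them planted in
clusters of 3 (adjacent gaps drawn below `cluster_gap_bp` = 5 kb, isolated
loci ≥ 12 kb from anything); 48 female + 1 male small-RNA libraries of
20,000 reads by default; 6 planted 10-fold male-biased miRNAs; 400 genes
(3 vs 3 mRNA replicates) with 40 planted 16-fold DE genes, half per
direction. Counts are NB with `var = μ + αμ²` (miRNA default α = 0.02,
mRNA α = 0.01). X-linked loci get a 0.5× mean multiplier in both sexes,
emulating the observed lower X expression. All outputs are pure functions
of (config, seed).

Choices that make recovery tests exact rather than probabilistic:

- uniform ACGT composition; rejection sampling guarantees each precursor
  occurs exactly once in the genome (both strands) and that non-target UTRs
  contain no seed match for any biased miRNA;
- planted male-biased miRNAs are modeled as near-male-specific: a fixed low
  female baseline (0.2× the typical depth share) with the male mean
  `bias_fold` times higher. This matches the empirical pattern (biased
  miRNAs barely expressed in females) and keeps the male library's
  compositional shift small, so the planted ratio survives CPM
  normalization with margin;
- biased miRNAs are drawn from isolated loci: single-family cluster members
  share a mature sequence, and the deterministic counting tie-break would
  collapse their reads onto one member;
- planted target sites embed the reverse complement of mature positions
  2–19 (18 nt), not just the 7-mer seed, so the planted duplex is below
  −15 kcal/mol for *any* base composition (17 stacks × −0.93 worst case)
  and survives every profile; the seed reverse complement still sits
  verbatim at the recorded offset. Flanks are rejection-sampled so the site
  neither extends nor duplicates;
- decoy reads are invalid in exactly one way — out-of-range length (17 or
  36 nt) with good qualities, or in-range length with all qualities below
  the cutoff — never both, so the read filter removes all of them and none
  of the signal;
- the exact-recovery conditions (the `recovery` preset) use α = 0 and
  depth 100,000, under which the planted 10-fold bias clears the 5× rule
  with a measured worst-case margin of ≈ 1.35 across seeds.

Not emulated: RNA secondary structure of precursors (star sequences are
random, not reverse-complementary arms), sequencing errors beyond the
quality decoys, isomiRs, multi-mapping beyond the tie-break, female
tissue/stage structure (all female libraries are exchangeable), and batch
effects. Passing recovery tests therefore demonstrates the correctness of
the decision rules and their composition, not robustness to alignment
artifacts or biological heterogeneity in real libraries.

## Numerical and interface conventions

- Coordinates 0-based half-open internally; GFF3 1-based inclusive; FASTQ
  qualities Sanger Phred+33.
- CPM columns sum to 10⁶ within 10⁻⁶ relative tolerance whenever a sample
  has matched reads.
- Thresholds are inclusive where the rule says "at least"/"or higher"
  (score ≥ 1, reads ≥ 30, ratio ≥ k, energy ≤ threshold) and exclusive for
  the cluster gap (< 10 kb) and the DE fold filter (> 4).
- Degenerate inputs: empty locus sets, all-zero samples, UTRs shorter than
  the seed and genes with all-zero counts are handled (empty outputs,
  warnings, or exclusion) rather than raised, except where the request is
  contradictory (no male sample, zero library depth, loci that cannot fit
  the genome at the required spacing), which raise informative errors.
- Problem sizes in tests and in `scripts/acceptance.py` (60 loci, 49
  libraries, 400 genes, 50 calibration replicates of 120 genes) are the
  package's simulation design: large enough that every planted structure is
  recoverable with margin, small enough to iterate on quickly.
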