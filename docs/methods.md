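# Methods

## Problem setting

Affinity-enrichment sequencing of 5-hydroxymethylcytosine (5hmC) yields,
per sample, a set of called peaks — genomic intervals significantly
enriched for 5hmC.  Peak sets vary strongly between individuals, so
cohort-level analysis works on *5hmC blocks*: maximal genomic intervals
where at least `min_support` samples of a cohort (default 2) show peak
occupancy.  Blocks are the unit for all downstream statistics: feature
and chromosome enrichment, developmental (cohort-exclusive) comparison,
expression- and pathway-linked enrichment, and base-resolution TAB-Seq
validation.

All coordinates are 0-based half-open (BED convention) on a declared
genome; intervals on undeclared chromosomes are errors, not silently
dropped.  Interval sets are kept normalized — sorted, disjoint, with
bookended neighbours merged, because a block is defined by base support
and two abutting equal-support runs form one continuous interval.
Strand enters only through transcription start sites (regulatory
domains); interval arithmetic ignores it.

## Block construction and metrics

`call_blocks` computes the per-base sample-support profile by a sweep
over peak boundaries and keeps maximal runs with support ≥ min_support.
Each block then carries: `n_positive` (samples with ≥ 1 bp of peak in the
block), `sum_peak_bp` (summed *full* lengths of every overlapping peak
across positive samples; an in-block-clipped variant is available via
`clip_to_block=True`) and `sum_reads` (summed per-peak read counts, 0
when absent).  A peak overlapping two blocks is credited to both — no
splitting.  Peak-sharing degrees are per peak over the pooled peak list:
the number of samples (including the peak's own) overlapping it by
≥ 1 bp.

Cohort-exclusive blocks use block-level exclusivity: a block is
fetal-only iff it overlaps no adult block by even 1 bp.  A base-level
variant (`cohort_specific_bases`, subtract then keep fragments ≥ L bp)
is provided for sensitivity analysis.

## Enrichment statistic and null model

Enrichment is base-pair weighted:

    fold = (block bp in feature / total block bp) / (feature bp / genome bp)

with 1 the reference rate.  Blocks vary over two orders of magnitude in
length, so bp weighting is the defensible default; a crude count-weighted
variant exists behind a flag.  The permutation null re-places every
block, length preserved, uniformly at random: chromosome chosen with
probability proportional to its length among chromosomes long enough to
hold the block, start uniform on `[0, L - len]`, placed blocks allowed to
overlap (their feature overlaps are summed with multiplicity so the
expectation stays linear and equal to the closed form).  Empirical
p-values use the two-sided `(r + 1)/(n + 1)` estimator, so they are never
zero.  The placement start being confined to `[0, L - len]` introduces an
edge bias of order `len/L`; with default block lengths ≤ 1.8 kb on 1 Mb
chromosomes this is ≤ 0.2% and far below Monte-Carlo error at
n_perm = 1000.

CpG-island shores are the standard definition: 2 kb flanks on each side
of an island, minus the islands.  Expression-class and developmental-group
enrichment restrict the reference space to the union of analyzed gene
bodies (TSS→TES), so a uniformly genic block set has fold 1 in every
class; classes with zero gene-body bp are omitted with a warning.

## Expression classes and groups

Genes are summarized per cohort by the median of normalized linear-scale
values.  "Silent" means median below a threshold.  The package default
threshold is the 5th percentile of pooled cohort medians, a fallback for
data whose detection limit is unknown; the pipeline, which analyses
simulated data with a known detection limit, passes the generator's
explicit threshold (1.0) instead — the percentile rule misclassifies when
the truly-silent fraction differs from 5%.  Non-silent genes split into
tertiles (low/intermediate/high) of the cohort median, ties broken by
gene id so class sizes are balanced to within one gene.  Developmental
groups: I fetal-expressed/adult-silent, V the converse, II/IV ≥ 2-fold
biased (boundary inclusive, linear scale), III within 2-fold both ways,
silent-in-both unassigned.

## Regulatory domains and term tests

Each gene's basal domain is 5 kb upstream / 1 kb downstream of its TSS,
strand-oriented, clipped to the chromosome.  The extended domain grows
from the basal domain on each side until the nearest other gene's basal
domain, the chromosome end, or 1 Mb, whichever is closest; extensions
never invade a neighbour's basal domain, but extended domains may overlap
each other.  Curated-domain exceptions of the full GREAT tool are out of
scope.

The binomial region test reduces each query region to its midpoint
(any-overlap assignment behind a flag), counts midpoints inside the
term's normalized extended domains, and tests `P(X ≥ k)` for
`X ~ Binomial(n_regions, domain bp / genome bp)`; fold is `k/(n·p0)`.
The hypergeometric gene test draws the genes hit by ≥ 1 midpoint against
the term's membership within the gene universe.  Both test families are
BH-corrected separately; terms rank by raw binomial p with term-id
tie-break.

## TAB-Seq arithmetic

The oxidized sample's C/(C+T) ratio estimates 5hmC; the untreated
bisulfite ratio estimates 5mC + 5hmC; their difference estimates 5mC,
clipped at zero because sampling noise can drive it negative.  No
correction is applied for bisulfite non-conversion or oxidation
efficiency (hooks exist, defaulting to perfect efficiency).  Interval
summaries are unweighted means over the CpGs inside the interval;
concordance against sequencing calls uses a configurable
TAB-Seq-positivity threshold (default 0.1 hydroxymethylation).

## Synthetic data: what it emulates, and what it does not

The generator plants known truth at toy scale — 3 chromosomes × 1 Mb,
two cohorts of 8 and 7 samples, 150 consensus blocks per cohort (30%
shared between cohorts), per-sample detection probability 0.6, peak
boundary jitter ±50 bp, 15 sample-unique noise peaks per sample,
negative-binomial read counts (mean 50, dispersion 5).  Feature tracks
(genes 30% of the genome, CpG islands 3% with derived shores, enhancers,
repeats, miRNA, lncRNA) are placed non-overlapping within each track.
Peak/block placement is biased per feature by `bias^overlap_fraction`
(CGI 6×, genic 2×, repeats 0.1×): the exponent makes the planted effect
act on the base-pair footprint that the enrichment statistic measures.
Effect magnitudes and the block count were chosen by a power analysis so
that the planted directions are detectable above placement noise in
replicate runs of the default configuration; 150 blocks is also far
closer in spirit to the tens of thousands of blocks in real cohort data
than a few dozen would be.  Half of each cohort's exclusive blocks are
placed inside gene bodies of that cohort's developmentally biased genes
(groups I/II fetal, IV/V adult), and one gene set ("T000") collects the
hosts of the fetal-exclusive blocks.

Expression plants group sizes proportional to a real developmental liver
cohort (12/21/231/28/8 of 300 genes), baseline expression log-uniform on
[4, 64], silent level 0.1 against a detection limit of 1.0, a 3-fold
planted bias for groups II/IV (comfortably beyond the 2-fold
classification boundary under noise), and log-normal sample noise
σ = 0.2.  TAB-Seq counts are binomial draws at depth 500 from planted
(h, m) in one fetal-specific interval (4 CpGs, h ≈ 0.2–0.35 in fetal
samples) and one adult-specific interval (7 CpGs, h ≈ 0.45–0.6 in adult
samples), mirroring a fetal-only and an adult-only validation locus.

Not emulated: read-level data, GC/mappability bias, assembly gaps,
correlated inter-individual structure, probe-level microarray artifacts,
bisulfite conversion failure.  Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
generative model, not robustness to these real-data complications.

## Numerical and reproducibility choices

All randomness flows from one master seed; each generator stage derives
its stream as `default_rng([seed, stage_offset])`, so stages are
independently reproducible.  Problem sizes in the test suite (toy
genomes of ≤ 10 kb chromosomes for oracle comparisons, 20 replicate
simulations for direction checks, n_perm = 1000 for null calibration)
were chosen to keep the full suite in the tens of seconds while leaving
clear statistical margins.  Ties: tertile boundaries break by gene id;
term ranking breaks by term id; the 2-fold group boundary is inclusive
(exactly 2-fold counts as biased).  Degenerate inputs (empty block sets,
empty features, zero-depth TAB-Seq rows, all-silent cohorts) raise
errors naming the offending object rather than returning NaNs.

## Known limitations

Block-level exclusivity makes cohort-only counts sensitive to single-bp
overlaps; the base-level variant exists but is not the default.  The
permutation null is unconstrained by gaps or composition; on real
genomes a GC- or mappability-matched null would be stricter.  The
percentile silence rule is a heuristic — array detection p-values, where
available, are better.  `sum_peak_bp` double-counts peaks spanning two
blocks by design (field definition), so summing it across blocks can
exceed total peak bp.
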