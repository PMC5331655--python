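# Methods

## Model and procedure

The pipeline asks, per TE family, whether expression of individual
insertions is conserved between a query species and one or more target
species, and how much TE sequence ends up in lncRNAs. The unit of analysis
is the insertion-level TE *instance*: RepeatMasker fragments sharing a
RepeatMasker ID on one chromosome are joined into one instance whose span
runs from the first to the last fragment and whose `length_bp` is the
summed fragment length (the nested interloper is excluded — reads cannot
map to it, so it is also the RPKM denominator). Fragments with the same ID
on different chromosomes are never merged; cross-chromosome joining has no
biological meaning. Singleton fragments pass through unchanged.

Consensus divergence is converted to a 0–1000 similarity score with the
linear map `round(1000·(1 − percDiv/100))`; the published scaling behind
such scores is not specified, but every downstream use is ordinal (ranking
families by age), so any strictly monotone choice gives identical
conclusions. An instance's score is the length-weighted mean over its
fragments (robust to tiny fragments); a family's age surrogate is the
unweighted mean over instances.

Conservation is defined by liftover: among chains overlapping an interval,
the chain maximizing the interval bases inside aligned blocks wins (chain
score breaks ties; residual ties pointing at different loci are reported
ambiguous — a policy choice, since multi-chain behaviour is unspecified in
the tools this mirrors). The lift succeeds when the mapped fraction is at
least `minMatch` = 0.1, the standard between-species default, and the
target interval spans first-to-last mapped base (LiftOver's region
behaviour, not the union of mapped segments). An instance is *putatively
conserved* when it lifts **and** the lifted locus overlaps ≥ 1 bp of any TE
annotated in the target genome; requiring the same family is deliberately
not part of the definition (the annotation-in-target criterion is the
operative one), but the same-family flag is recorded and exposed through
`reannotation_concordance` as a validation statistic.

Expression uses coverageBed semantics — a read interval overlapping a
feature by ≥ 1 bp counts, multi-feature reads count once per feature — and
RPKM = count·10⁹/(length·library size). Two rules coexist by design: TEs
are expressed when the replicate-mean RPKM ≥ 1; transcripts must reach
RPKM ≥ 1 in every replicate (strictly stricter). Both thresholds are
inclusive. Counting is unstranded by default; strand-aware counting is not
implemented because the coverage step being emulated is unstranded.

### Family-level enrichment

For one query/target pair, each family contributes a summary: `total`
(coding-clean instances), `i` = query-expressed, conserved count, `K` =
conserved instances whose ortholog is expressed in the target, and `j` =
query-expressed instances with an expressed ortholog. The reported
proportion is `j/i` (undefined and reported as null when `i` = 0). The
enrichment p-value is the hypergeometric survival function P(X ≥ j) with
population N = conserved instances, successes K, and draws n =
query-expressed among conserved — this directly tests association between
query and target expression among orthologs. The published tables this
mirrors do not print N and K, so the parameterization is a documented
choice; the alternative (population = all instances, successes = conserved)
is available behind `population="all"`, and printed p-values from other
implementations are not expected to match numerically. The tail is summed
in log space via `logsumexp` of exact log-pmfs; `j = 0` returns exactly
1.0 and `j > min(K, n)` exactly 0.0. No multiple-testing correction is
applied by default (raw p-values are the convention for these tables); a
Benjamini–Hochberg column is optional.

Family filters default to: total ≥ 100, query-expressed ≥ 30, main classes
only (DNA/SINE/LINE/LTR), simple repeats and low-complexity annotation
excluded. Small families yield unstable significant p-values and
simple/low-complexity repeats sit in GC-biased regions; both effects
motivate the exclusion.

### Null calibration of the discrete test

The hypergeometric statistic is discrete: raw survival-function p-values
are exactly uniform only on their attainable levels, and at family sizes of
a few hundred the largest pmf step (~0.08) alone approaches the
Kolmogorov–Smirnov critical value for 200 families. Uniformity under the
null is therefore audited with the randomized probability-integral
transform u = sf(j+1) + U·pmf(j), which is exactly Uniform(0,1) under
independence for any degree of discreteness (`randomized_null_pit`). The
p-values reported in tables remain the raw, conservative tail
probabilities.

### lncRNA catalog and TE annotation

The filter cascade removes, in order: blacklisted biotypes (default:
protein_coding, pseudogene and its `*_pseudogene` subtypes, tRNA, rRNA,
snRNA, snoRNA, miRNA, misc_RNA — a documented default, since blacklists are
project-specific), mono-exonic transcripts (systematic assembly false
positives), and transcripts with coding potential ≥ cutoff. The default
cutoff 0.364 is a widely used human value for CPAT-style scores and is
documented as arbitrary; the score itself comes from a `coding_potential`
input attribute when present, otherwise from a transparent stand-in: the
longest forward-frame ORF (ATG through an in-frame stop, stop required)
divided by transcript length. The stand-in is pluggable (`scorer=`) for a
trained coding-potential model.

TE annotation records an exon/TE intersection only when it covers ≥ 10% of
the exon; the transcript's dominant TE is the instance with the largest
total overlap (ties: larger single-exon overlap, then lexicographic family
name). For contribution statistics, overlapping TE annotations within an
exon are resolved by assigning each base to the instance with the longest
local overlap before summing, so class proportions never double-count a
base and sum to ≤ 1 of the exonic sequence of TE-overlapping transcripts;
`allow_double_count=True` restores raw intersectBed `-wao` summation for
comparability with that tool. Normalized family contribution is the
family's share of lncRNA exonic bp divided by its share of the genome.

Cross-species lncRNA conservation lifts the whole transcript span as one
interval (transcript-level counts); exons are lifted individually only to
re-apply the 10% TE rule against the target's own TE annotation. Expression
in the target is quantified over the lifted span in target coordinates with
the all-replicates rule — reciprocal catalog construction is out of scope,
and lifted-coordinate quantification is the choice implemented. Reported
percentages are fractions of the *lifted* count (this matches how such
lift tables are conventionally printed). Tiers partition the catalog:
`all_species` (lifted and expressed in every target), `some_nhp` (in at
least one), `query_only`.

## Synthetic data: what it emulates, and what it does not

Species are pure coordinate spaces related by chain files; no genomic
sequence exists (only short synthetic transcript sequences feed the
coding-potential stand-in). The generator plants, per family: retention
(each target loses each instance independently with `lossProbPerBranch`,
so an age ladder of families reproduces the young-families-are-less-
conserved trend), query expression (`exprProbQuery`), and target expression
of retained instances (`exprCorrelation` given query expression, the
marginal probability otherwise — setting correlation equal to the marginal
yields exact independence, the calibration null). Retained instances sit in
aligned chain blocks with occasional ≤ 20 bp indels (mapped ratio stays
≥ 0.9, exercising minMatch logic without defeating it); lost instances fall
in source gaps. About 10% of instances are emitted as two fragments sharing
an ID to exercise joining, and ~5% carry a planted coding overlap to
exercise the coding filter.

Reads are fixed-length (100 bp) BED intervals — one record per counted
fragment; paired-end structure, quality values, mappability and alignment
error are not simulated. Counts are Poisson at a planted RPKM of 20 for
expressed features, floored so RPKM ≥ 1.2 holds in every replicate at the
nominal library size, and Poisson at RPKM 0.01 for silent features; a
featureless filler region absorbs the rest of the library so per-replicate
library sizes are exact. Replicate structure defaults to 3/1/2/1 across
four species, mirroring a realistic multi-species iPSC design. TE-derived
transcripts are planted on TE instances chosen with class weights
(LTR 3.0, LINE 2.5, DNA 1.0, Other 1.0, SINE 0.3), reproducing LTR/LINE
enrichment and SINE depletion among exapted elements; a TE-derived
transcript's expression is coupled to its TE's expression in every species,
which is both the biological story and what keeps span-level read counts
consistent with the planted flags.

Consequences for interpretation: passing tests show the *pipeline logic*
is correct under the planted statistical structure — they say nothing about
alignment artifacts, mappability of repetitive sequence, assembly quality
differences between species, or GC bias, all of which affect real data and
none of which are simulated. Default per-family expression probabilities
(0.3) are chosen for test power, not measured realism.

## Numerical and procedural choices

* Coordinates are 0-based half-open everywhere after parsing; RepeatMasker
  begin columns are 1-based inclusive and converted on input; GTF is
  1-based inclusive and converted by the reader/writer pair. Touching
  intervals do not overlap.
* Read counting uses sorted boundary arrays (#starts < feature end minus
  #ends ≤ feature start), exact for ≥ 1 bp overlap regardless of feature
  overlap structure, and O((N+M)·log N).
* Chain lifting binary-searches an indexed block array per chain, so
  whole-genome chains with 10⁵ blocks lift single intervals in
  microseconds; tests compare against a per-base enumeration oracle.
* Negative-strand chains follow the far-end coordinate convention; lifted
  intervals are always reported on the target forward strand with a strand
  flag.
* Zero-length intervals, empty catalogs and zero-denominator ratios raise
  typed errors (`ValidationError`, `UndefinedStatisticError`) rather than
  returning 0 or NaN.
* Benchmarks in the test-suite and acceptance script use 10 families ×
  250–400 instances over four species (planted recovery) and 200
  independence families over two species (calibration), with 150k reads
  per replicate — sizes at which every planted effect is detectable with
  wide margins while a full run takes seconds.

## Known limitations

* The coding-potential stand-in is a deliberately simple ORF-fraction
  score; it separates planted coding from planted non-coding sequence but
  is not a calibrated classifier for real transcripts.
* `ambiguous` lift results are counted as not lifted downstream; no
  chain-net reconciliation is attempted.
* Target-expression of a conserved TE is the expression of the
  best-overlapping target instance; partial-overlap orthology (one query
  instance split across two target instances) credits only the larger
  piece.
* lncRNA conservation quantifies expression over the lifted span, which
  includes intronic sequence; a target-side exon-level quantification would
  be stricter.
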