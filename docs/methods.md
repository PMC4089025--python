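# Methods

## Coordinate and pairing conventions

All coordinates are 0-based half-open (BED). The TSS of a plus-strand gene is
its `start`; of a minus-strand gene its `end`. Overlap requires ≥ 1 shared
base: touching intervals do not overlap. An H2H pair is a minus-strand gene
whose TSS lies at or left of a plus-strand gene's TSS on the same chromosome
with TSS distance strictly below `max_tss_distance` (default 1000 bp).
Because a curated pair database was the original source of such pairs and no
published rule covers ambiguous neighbourhoods, the deriver makes the choice
explicit: each gene joins at most one pair, the smallest TSS distance wins,
ties break lexicographically on `pair_id` (= the two gene ids sorted and
joined with `:`). Overlapping TSSs (plus TSS left of minus TSS) are rejected
by default; `Thresholds(allow_overlapping_tss=True)` relaxes this. The H2H
block is the min-start..max-end span of the two gene bodies — this also
defines blocks for pairs whose bodies overlap, a case the block definition
does not otherwise address. A gene's *background region* is its body plus
`upstream_bp` (default 100) upstream of the TSS, clipped at 0.

## Binding annotation

`annotate_binding` marks cell (factor, pair) = 1 when any peak overlaps the
pair's block, via a per-chromosome interval tree; the result is defined to
equal the naive all-vs-all check (and is tested against it). No
minimum-overlap fraction or peak-score weighting is applied. Binding
fractions use **all supplied pairs** as denominator, not only pairs bound by
≥ 1 factor — the published summary tables are ambiguous between the two
conventions, and callers who want the bound-only denominator can subset the
matrix first. Overrepresentation is strict (> threshold, default 0.45).
Histone/DNase annotation reuses the same code path with a different factor
class.

## TF clustering and co-occurrence

Profile similarity is Pearson correlation between binary rows; zero-variance
rows are excluded (warned), and any residual undefined correlations are set
to 0 so their dissimilarity is 1. Clustering is Ward linkage on `d = 1 − r`
(scipy's Ward update on the condensed dissimilarity; no published variant is
specified, and this is the common default). The k-group cut uses
`fcluster(..., maxclust)`; rows are canonically ordered by factor name first
so the partition is independent of input order.

The co-occurrence null is the independence model: with `n` pairs total and
marginals `n_A`, `n_B`, the shared count is referred to
`Binomial(n, (n_A/n)(n_B/n))`, one-sided upper tail. The published recipe
names a binomial test without stating the null; the product-of-marginals
independence null is the standard choice and is configurable territory for
forks — results on identical data may differ edge-for-edge from any other
null. "Regulating at least 10 gene pairs" is read as *each* TF of the tested
pair binding ≥ 10 pairs. No multiple-testing correction is applied by
default (none is applied in the source analysis); `bonferroni=True` is
available.

## Spatial inter-H2H pairs

A locus overlapping two or more blocks contributes every valid combination
(the source analysis does not say how multi-block loci were handled; emitting
all combinations is the lossless choice, deduplicated with supporting record
indices kept). "Fully annotated" counts records with both loci hitting ≥ 1
block, whether or not the two ends name different pairs. Inter-pair TF sets
are unions over the two members; TF similarity is Jaccard with 0/0 defined
as 0. The random-pair null draws unordered distinct gene pairs uniformly
(n = 10,000 by default, seeded); since TF binding is only defined for H2H
*pairs* in the source, gene-level TF sets for this null use background-region
overlap — an interpretation, documented here. Fold changes are computed from
unrounded fractions and displayed at two decimals; TFs with zero intra
fraction sort last with an undefined fold change.

## Markers and chi-square

Marker proportions compare pair-level counts (blocks) against gene-level
counts (background regions) — different units, implemented as specified with
this caveat noted. The test is Pearson chi-square on the 2×2
observed/not-observed table, 1 df, no continuity correction by default
(Yates optional); any zero expected cell yields an undefined (NaN) result
rather than a statistic.

## Co-expression connectivity

Edges keep mutual rank MR ≤ `mr_max` (inclusive, default 20); all supplied
genes stay as nodes so singletons count with degree 0. Duplicate symmetric
MR records collapse to the smaller value. The two-group location test is the
Mann–Whitney rank-sum (greater-tail): the source names a signed-rank test,
which is a paired test and undefined for two independent groups of unequal
size, so the rank-sum analogue is used and the substitution is documented; no
paired option is provided. The resampling null draws `n_resamples` gene sets
of size |H2H| without replacement within a draw (independent across draws,
one seeded generator), scores each by mean degree, and reports
`empirical_p = P(resample mean ≥ observed mean)`. Draws are vectorised in
chunks (random keys + argpartition) so 10,000 resamples over 20,000 genes
take seconds.

## Synthetic data model

The generator's defaults are the study conditions: 20,000 genes on 10
chromosomes of 15 Mb, 1,500 H2H pairs (TSS distance ~ U(50, 999) bp), gene
bodies ~ U(1, 3) kb, intergenic gaps ~ U(2, 4) kb so no accidental divergent
pair arises; 45 TFs (17/12/16 bidirectional/spatial/neutral); 10 markers
(8 activating, 2 repressive); 500 locus pairs of which 21% (105) join two
distinct planted blocks; 150,000 MR records ~ U(1, 40) giving a mean degree
near 7 after the MR ≤ 20 cut.

Two latent structures make the planted signal detectable by the actual
statistics rather than by construction:

* **Block activity.** Each block is active with probability 0.5.
  Bidirectional TFs bind active blocks at 0.85 and inactive ones at their
  gene-level rate (0.05). Independent Bernoulli rows with equal rates are
  uncorrelated regardless of rate, so without a shared latent state
  correlation-based clustering could not separate classes; activity gives
  bidirectional TFs pairwise r ≈ 0.5 and an expected binding fraction of
  ~0.45–0.5 (straddling the overrepresentation cutoff the way the real
  overrepresented set does).
* **Interacting-block sharing.** Spatial TFs bind blocks of planted
  interacting pairs at `spatial_share_boost × 0.2` (default boost 2.0) and
  other blocks at 0.2, which raises both the TF similarity of interacting
  inter-pairs and the spatial class's inter/intra fold change.

Neutral TFs bind independently (blocks 0.15, genes 0.08). Marker rates:
activating 0.45 on background regions and `min(0.95, 0.45 × boost)` on
blocks (boost default 1.8); repressive 0.15 / 0.08. The co-expression
sampler upweights H2H endpoints by `h2h_degree_boost` (default 1.5, near the
observed mean-degree ratio in the real network).

Each generator owns a `default_rng([seed, label])` stream with a fixed
label, so adding or re-running one generator never changes another's output;
datasets are byte-identical across runs of the same seed.

What the generator does **not** emulate: distance decay of chromatin
contacts, peak-width/score distributions of real ChIP-seq, transcript-level
isoform structure, and realistic co-expression covariance (edges are
independently sampled, not derived from an expression model). Passing
recovery tests therefore demonstrates correctness of the statistics and
pipelines under the planted model, not performance on real data.

## Problem sizes in tests

Recovery tests run the same effect sizes at reduced counts chosen for quick
iteration: clustering recovery at 2,000 genes / 300 pairs over 20 seeds;
similarity recovery on the 400-gene desk-scale config over 100 replicates
with a 200-pair null per replicate; degree power and null calibration at
2,000 genes / 200 pairs with 1,000 resamples over 100 seeds. One end-to-end
test and the acceptance script run the full default scale, which completes
in well under a minute per stage on one core.

## Known limitations

* The binomial independence null ignores between-pair dependence (nearby
  blocks share chromatin context in real data), so co-occurrence p-values
  are anti-conservative in that respect.
* Pair-vs-gene denominators in the marker comparison are heterogeneous, as
  in the source analysis.
* The adjacency rule for ambiguous H2H neighbourhoods is a package
  convention; curated pair sets may differ.
* `empirical_p` is a discrete statistic with resolution `1/n_resamples`;
  its null distribution is only approximately uniform.
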