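# h2hreg — transcriptional regulation of head-to-head gene pairs

`h2hreg` is an analysis toolkit for **head-to-head (H2H) gene pairs**: adjacent
genes on opposite strands transcribed divergently, with transcription start
sites (TSSs) less than 1 kb apart. The region between the two TSSs is the
*bidirectional promoter*; the interval spanning both gene bodies and the
promoter is the *H2H block*. The package is aimed at regulatory genomicists
who want to ask, from gene models, ChIP-seq/DNase peak sets, Hi-C-style
interacting locus pairs and a co-expression table:

1. **Which factors bind H2H pairs?** A TF binds a pair when any of its peaks
   overlaps the pair's block (≥ 1 bp, 0-based half-open BED coordinates).
   This yields a binary TF × pair matrix, per-TF binding fractions, and the
   set of *overrepresented* TFs (binding > 45% of pairs).
2. **How are TFs structured?** Binding profiles are clustered with Pearson
   correlation and Ward linkage (dissimilarity `d = 1 − r`), and a TF
   co-occurrence network is built: for TFs A, B binding `n_A`, `n_B` of `n`
   pairs with `s` shared, the edge is kept when the one-sided binomial tail
   `P(X ≥ s)`, `X ~ Bin(n, (n_A/n)(n_B/n))`, is below 0.01 **and** the overlap
   ratio `s / |A ∪ B|` exceeds 0.6, with each TF binding ≥ 10 pairs.
3. **Which H2H pairs interact spatially?** Each locus of an interacting locus
   pair is annotated with the H2H blocks it overlaps; a record whose two loci
   hit *different* blocks defines an **inter-H2H pair**. The TF set of an
   inter-H2H pair is the union over its two members; TF similarity between
   any two gene(-pair) units is the Jaccard index `|A ∩ B| / |A ∪ B|`,
   compared against a null of random gene pairs (gene TF sets from peak
   overlap with the gene body + 100 bp upstream). Per-TF enrichment is the
   fold change (inter-pair binding proportion) / (intra-pair binding
   proportion).
4. **Are H2H blocks epigenetically active?** Marker (DNase/histone)
   proportions on H2H pairs versus background genes, Pearson chi-square on
   the 2×2 observed/not-observed table.
5. **Are H2H genes hubs?** A co-expression graph keeps gene pairs with
   mutual rank MR ≤ 20; H2H-gene degrees are compared to all other genes by
   a Mann–Whitney rank-sum test and by resampling: 10,000 random gene sets
   of the same size, empirical p = fraction of draws whose mean degree
   reaches the observed H2H mean.

A seeded synthetic-data generator (`h2hreg.simulate`) emulates all four input
classes with planted ground truth — divergent pairs, three TF classes
(bidirectional / spatial / neutral), activating and repressive markers,
locus pairs joining planted block pairs, and a degree-boosted co-expression
table — so every stage is testable end to end without downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
dataset at study scale (20,000 genes, 1,500 H2H pairs, 45 TFs, 10 markers,
500 locus pairs):

```bash
python analysis/01_simulate.py
python analysis/02_annotate_binding.py
python analysis/03_tf_structure.py
python analysis/04_spatial_interactions.py
python analysis/05_epigenetic_markers.py
python analysis/06_coexpression.py
```

Output (seed 1):

```
1500 H2H pairs; 1500 bound by >= 1 of 45 TFs
17 overrepresented TFs (>45% of pairs): BID06, BID17, ...
TFs clustered into 2 groups with sizes [28, 17]
co-occurrence network: 128 edges among 17 TFs
105 locus-pair records fully annotated by H2H blocks; 105 distinct inter-H2H pairs
mean TF similarity: 0.282 (interacting) vs 0.039 (random gene pairs, n=10000)
top fold-change TFs:
  SPA04: intra 30.7% inter 81.0% fold 2.63
  ...
degrees: H2H median 10 / mean 10.2; other median 7 / mean 6.8
rank-sum p = 0; resampling empirical p = 0 over 10000 draws
```

Reading this: the 17 planted bidirectional-promoter TFs are exactly the
overrepresented set and form their own Ward cluster and a dense co-occurrence
core; the 105 locus-pair records planted across distinct blocks are recovered
as 105 inter-H2H pairs whose members share far more TFs (Jaccard 0.28) than
random gene pairs (0.04); spatial-class TFs top the inter/intra fold-change
ranking; activating markers cover ~94% of blocks versus ~48% of background
genes (chi-square p ≪ 0.01); and H2H genes are better connected in the
co-expression graph than other genes.

Each stage is also exposed as a CLI over a YAML config:

```bash
h2hreg simulate --seed 1 --out data/
h2hreg all --config data/run_config.yaml
```

Report tables (TSV with a threshold-documenting header), the dendrogram
(Newick) and the co-occurrence network (GraphML/SIF) land in the configured
output directory together with a machine-readable run manifest.

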