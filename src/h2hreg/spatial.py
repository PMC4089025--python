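"""Spatially interacting inter-H2H pairs from Hi-C-style locus pairs.

Each locus of an interacting locus pair is annotated with every H2H pair whose
block it overlaps.  A record whose two loci are annotated with different H2H
pairs yields an inter-H2H pair; the TF set of an inter-H2H pair is the union
of the member pairs' TF sets, and the TF similarity of any two-gene(-pair)
unit is the Jaccard index of the two TF sets.  The null model for similarity
draws random gene pairs from the whole gene set, with gene-level TF sets
defined by peak overlap with the gene's background region (gene body + 100 bp
upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import BindingMatrix, annotate_intervals
from .genome import GeneModel, H2HPair, background_region, h2h_block
from .io import LocusPairFile, PeakFile

__all__ = [
    "InterH2HPair",
    "InterH2HResult",
    "SimilaritySummary",
    "annotate_loci",
    "find_inter_h2h",
    "inter_binding_set",
    "tf_similarity",
    "interacting_similarity",
    "gene_binding_matrix",
    "random_inter_null",
    "fold_change",
    "enrichment_table",
]


@dataclass(frozen=True)
class InterH2HPair:
    """Two distinct H2H pairs linked by at least one interacting locus pair."""

    pair_a: str
    pair_b: str
    supporting_loci: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pair_a == self.pair_b:
            raise ValueError("inter-H2H members must be distinct")
        if not self.supporting_loci:
            raise ValueError("inter-H2H pair needs >= 1 supporting locus record")


@dataclass
class InterH2HResult:
    """Inter-H2H pairs plus the count of locus records fully annotated by H2H
    pairs at both ends (whether or not the ends name different pairs)."""

    inter_pairs: list[InterH2HPair]
    fully_annotated: int


@dataclass
class SimilaritySummary:
    """TF-similarity score distribution for one group of gene(-pair) pairs."""

    group: str
    scores: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores)) if len(self.scores) else 0.0


def annotate_loci(
    locus_pairs: LocusPairFile, pairs: Sequence[H2HPair]
) -> list[tuple[set[str], set[str]]]:
    """For each locus-pair record, the sets of H2H pair_ids whose blocks
    overlap locus 1 and locus 2 respectively."""
    from intervaltree import IntervalTree

    blocks = [h2h_block(p) for p in pairs]
    pair_ids = [p.pair_id for p in pairs]
    trees: dict[str, IntervalTree] = {}
    for j, blk in enumerate(blocks):
        trees.setdefault(blk.chrom, IntervalTree()).addi(blk.start, blk.end, j)

    def hits(iv) -> set[str]:
        tree = trees.get(iv.chrom)
        if tree is None:
            return set()
        return {pair_ids[h.data] for h in tree.overlap(iv.start, iv.end)}

    return [(hits(a), hits(b)) for a, b, _ in locus_pairs.records]


def find_inter_h2h(
    annotations: Sequence[tuple[set[str], set[str]]]
) -> InterH2HResult:
    """Collect unique unordered inter-H2H pairs from per-locus annotations.

    Every record where both loci hit >= 1 block counts as fully annotated; each
    cross combination of distinct pair_ids across the two loci contributes an
    inter-H2H pair, deduplicated with supporting record indices accumulated.
    """
    support: dict[tuple[str, str], set[int]] = {}
    fully = 0
    for idx, (set_a, set_b) in enumerate(annotations):
        if not set_a or not set_b:
            continue
        fully += 1
        for pa in set_a:
            for pb in set_b:
                if pa == pb:
                    continue
                key = (pa, pb) if pa < pb else (pb, pa)
                support.setdefault(key, set()).add(idx)
    inter = [
        InterH2HPair(a, b, tuple(sorted(loci)))
        for (a, b), loci in sorted(support.items())
    ]
    return InterH2HResult(inter_pairs=inter, fully_annotated=fully)


def inter_binding_set(matrix: BindingMatrix, inter: InterH2HPair) -> set[str]:
    """TFs binding either member pair (union) — the inter-H2H binding set."""
    return matrix.factors_binding(inter.pair_a) | matrix.factors_binding(inter.pair_b)


def tf_similarity(set_a: set[str], set_b: set[str]) -> float:
    """Jaccard similarity |A n B| / |A u B|; 0 when both sets are empty."""
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


def interacting_similarity(
    matrix: BindingMatrix, inter_pairs: Sequence[InterH2HPair]
) -> SimilaritySummary:
    """TF similarity between the two member pairs of each interacting
    inter-H2H pair."""
    scores = np.array(
        [
            tf_similarity(
                matrix.factors_binding(ip.pair_a), matrix.factors_binding(ip.pair_b)
            )
            for ip in inter_pairs
        ],
        dtype=float,
    )
    return SimilaritySummary(group="interacting", scores=scores)


def gene_binding_matrix(
    genes: Sequence[GeneModel], peaksets: Sequence[PeakFile], upstream_bp: int = 100
) -> BindingMatrix:
    """Factor x gene binding matrix via background-region overlap (gene body
    plus ``upstream_bp`` upstream of the TSS)."""
    regions = [background_region(g, upstream_bp) for g in genes]
    m = annotate_intervals(peaksets, regions)
    return BindingMatrix(m.factors, [g.gene_id for g in genes], m.values)


def random_inter_null(
    genes: Sequence[GeneModel],
    peaksets: Sequence[PeakFile],
    n: int,
    seed: int,
    upstream_bp: int = 100,
) -> SimilaritySummary:
    """TF-similarity null from ``n`` random gene pairs.

    Each draw picks two distinct genes uniformly; a gene's TF set is the set of
    factors with a peak overlapping its background region.  Reproducible from
    ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(genes) < 2:
        raise ValueError("need at least two genes for random pairs")
    gm = gene_binding_matrix(genes, peaksets, upstream_bp)
    x = gm.values.astype(bool)  # factors x genes
    rng = np.random.default_rng(seed)
    n_genes = len(genes)
    a = rng.integers(0, n_genes, size=n)
    b = rng.integers(0, n_genes - 1, size=n)
    b = np.where(b >= a, b + 1, b)  # distinct partner, uniform over the rest
    inter = (x[:, a] & x[:, b]).sum(axis=0)
    union = (x[:, a] | x[:, b]).sum(axis=0)
    scores = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return SimilaritySummary(group="random", scores=scores.astype(float))


def fold_change(intra_fraction: float, inter_fraction: float) -> float:
    """Enrichment fold change inter/intra; NaN (undefined) when the intra
    fraction is zero."""
    if intra_fraction == 0:
        return float("nan")
    return inter_fraction / intra_fraction


def enrichment_table(
    matrix: BindingMatrix, inter_pairs: Sequence[InterH2HPair]
) -> pd.DataFrame:
    """Per-factor intra vs inter binding proportions and fold changes.

    intra_fraction: proportion of all H2H pairs in the matrix bound by the
    factor.  inter_fraction: proportion of inter-H2H pairs bound (union over
    the two members).  Fold changes are computed from unrounded fractions and
    also shown rounded to two decimals; undefined fold changes (intra = 0)
    sort last.
    """
    if not inter_pairs:
        raise ValueError("need at least one inter-H2H pair")
    n_pairs = len(matrix.pairs)
    n_inter = len(inter_pairs)
    inter_sets = [inter_binding_set(matrix, ip) for ip in inter_pairs]
    rows = []
    for i, f in enumerate(matrix.factors):
        intra = float(matrix.values[i].sum()) / n_pairs
        inter = sum(1 for s in inter_sets if f in s) / n_inter
        fc = fold_change(intra, inter)
        rows.append(
            {
                "factor": f,
                "intra_fraction": intra,
                "inter_fraction": inter,
                "fold_change": fc,
                "intra_pct": round(100 * intra, 1),
                "inter_pct": round(100 * inter, 1),
                "fold_change_display": round(fc, 2) if np.isfinite(fc) else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df["_undef"] = ~np.isfinite(df["fold_change"])
    df = df.sort_values(
        ["_undef", "fold_change", "factor"], ascending=[True, False, True]
    ).drop(columns="_undef")
    return df.reset_index(drop=True)
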