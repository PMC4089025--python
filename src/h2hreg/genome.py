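"""Genomic primitives for head-to-head (H2H) gene analysis.

A head-to-head pair is two adjacent genes on opposite strands transcribed
divergently with transcription start sites (TSSs) less than ``max_tss_distance``
apart (1 kb by default).  The region between the two TSSs is the bidirectional
promoter; the interval spanning both gene bodies and the promoter is the H2H
block.

All coordinates are 0-based half-open (BED convention).  Under this convention
the TSS of a plus-strand gene is its ``start`` and the TSS of a minus-strand
gene is its ``end``; touching intervals do not overlap.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "H2HPair",
    "Thresholds",
    "tss_of",
    "overlaps",
    "derive_h2h_pairs",
    "h2h_block",
    "bidirectional_promoter",
    "background_region",
    "make_pair_id",
]

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body with an identifier and a strand."""

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.strand not in STRANDS:
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class H2HPair:
    """A divergent gene pair: minus-strand gene transcribing leftward, plus-strand
    gene transcribing rightward, TSSs within the configured distance."""

    pair_id: str
    gene_minus: GeneModel
    gene_plus: GeneModel
    tss_distance: int

    def __post_init__(self) -> None:
        if self.gene_minus.strand != "-" or self.gene_plus.strand != "+":
            raise ValueError(f"pair {self.pair_id}: genes must be (-, +) stranded")
        if self.gene_minus.interval.chrom != self.gene_plus.interval.chrom:
            raise ValueError(f"pair {self.pair_id}: genes on different chromosomes")
        if self.tss_distance < 0:
            raise ValueError(f"pair {self.pair_id}: negative tss_distance")


@dataclass
class Thresholds:
    """All tunable cutoffs of the analysis, with the study defaults.

    max_tss_distance       divergent TSSs closer than this form an H2H pair (bp)
    overrepresentation_fraction  a TF binding strictly more than this fraction of
                           pairs is "overrepresented"
    cooccurrence_p         binomial p-value cutoff for co-occurrence edges
    overlap_ratio_min      minimum shared/union ratio for co-occurrence edges
    min_bound_pairs        each TF of a tested pair must bind at least this many pairs
    mr_max                 mutual-rank cutoff (inclusive) for co-expression edges
    upstream_bp            upstream extension defining a gene's background region (bp)
    n_resamples            random draws in the degree-comparison null
    n_random_pairs         random gene pairs in the TF-similarity null
    rng_seed               seed for every stochastic step
    """

    max_tss_distance: int = 1000
    overrepresentation_fraction: float = 0.45
    cooccurrence_p: float = 0.01
    overlap_ratio_min: float = 0.6
    min_bound_pairs: int = 10
    mr_max: float = 20.0
    upstream_bp: int = 100
    n_resamples: int = 10000
    n_random_pairs: int = 10000
    rng_seed: int = 0
    allow_overlapping_tss: bool = False

    def __post_init__(self) -> None:
        for name in ("max_tss_distance", "min_bound_pairs", "upstream_bp",
                     "n_resamples", "n_random_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("overrepresentation_fraction", "cooccurrence_p",
                     "overlap_ratio_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.mr_max <= 0:
            raise ValueError("mr_max must be positive")


def tss_of(gene: GeneModel) -> int:
    """Transcription start coordinate of a gene: the 5' end in half-open coords
    (``start`` for plus-strand genes, ``end`` for minus-strand genes)."""
    if gene.strand == "+":
        return gene.interval.start
    if gene.strand == "-":
        return gene.interval.end
    raise ValueError(f"gene {gene.gene_id!r} has invalid strand {gene.strand!r}")


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share at least 1 bp (half-open semantics; touching
    intervals do not overlap)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def make_pair_id(gene_id_a: str, gene_id_b: str) -> str:
    """Deterministic pair identifier: lexicographic join of the two gene ids."""
    lo, hi = sorted((gene_id_a, gene_id_b))
    return f"{lo}:{hi}"


def derive_h2h_pairs(
    genes: Sequence[GeneModel], thresholds: Thresholds | None = None
) -> list[H2HPair]:
    """Identify head-to-head pairs among a gene set.

    A minus-strand gene and a plus-strand gene on the same chromosome form a
    candidate when the minus TSS lies at or left of the plus TSS and the TSS
    distance is strictly below ``max_tss_distance``.  Each gene joins at most
    one pair; when several partners qualify, the smallest TSS distance wins,
    ties broken by pair_id.  The result is independent of input gene order.
    """
    thresholds = thresholds or Thresholds()
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)

    candidates: list[tuple[int, str, GeneModel, GeneModel]] = []
    max_d = thresholds.max_tss_distance
    for chrom_genes in by_chrom.values():
        plus = sorted(
            (g for g in chrom_genes if g.strand == "+"),
            key=lambda g: (tss_of(g), g.gene_id),
        )
        plus_tss = [tss_of(g) for g in plus]
        for m in chrom_genes:
            if m.strand != "-":
                continue
            t_m = tss_of(m)
            lo = t_m - max_d + 1 if thresholds.allow_overlapping_tss else t_m
            left = bisect.bisect_left(plus_tss, lo)
            right = bisect.bisect_left(plus_tss, t_m + max_d)
            for p in plus[left:right]:
                dist = abs(tss_of(p) - t_m)
                candidates.append((dist, make_pair_id(m.gene_id, p.gene_id), m, p))

    candidates.sort(key=lambda c: (c[0], c[1]))
    used: set[str] = set()
    pairs: list[H2HPair] = []
    for dist, pair_id, m, p in candidates:
        if m.gene_id in used or p.gene_id in used:
            continue
        used.add(m.gene_id)
        used.add(p.gene_id)
        pairs.append(H2HPair(pair_id=pair_id, gene_minus=m, gene_plus=p,
                             tss_distance=dist))
    pairs.sort(key=lambda pr: (pr.gene_minus.interval.chrom,
                               tss_of(pr.gene_minus), pr.pair_id))
    return pairs


def h2h_block(pair: H2HPair) -> GenomicInterval:
    """The H2H block: the interval spanning both gene bodies and the
    bidirectional promoter (min start to max end)."""
    a, b = pair.gene_minus.interval, pair.gene_plus.interval
    return GenomicInterval(a.chrom, min(a.start, b.start), max(a.end, b.end))


def bidirectional_promoter(pair: H2HPair) -> GenomicInterval | None:
    """The bidirectional promoter: the region between the two TSSs.

    Returns None when the TSSs coincide (empty interval); callers decide how to
    treat the degenerate case.
    """
    lo = tss_of(pair.gene_minus)
    hi = tss_of(pair.gene_plus)
    if hi == lo:
        return None
    return GenomicInterval(pair.gene_minus.interval.chrom, min(lo, hi), max(lo, hi))


def background_region(gene: GeneModel, upstream_bp: int = 100) -> GenomicInterval:
    """Gene body extended ``upstream_bp`` on the 5' side (strand-aware), clipped
    at coordinate 0.  Used to annotate arbitrary genes with peaks."""
    iv = gene.interval
    if gene.strand == "+":
        return GenomicInterval(iv.chrom, max(0, iv.start - upstream_bp), iv.end)
    return GenomicInterval(iv.chrom, iv.start, iv.end + upstream_bp)
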