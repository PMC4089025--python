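"""Genomic primitives: TSS convention, half-open overlap, H2H pair derivation,
block/promoter construction and background regions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from h2hreg.genome import (
    GeneModel,
    GenomicInterval,
    H2HPair,
    Thresholds,
    background_region,
    bidirectional_promoter,
    derive_h2h_pairs,
    h2h_block,
    overlaps,
    tss_of,
)
from .conftest import make_pair


@pytest.mark.parametrize(
    "strand,start,end,expected",
    [("+", 100, 500, 100), ("-", 100, 500, 500), ("+", 0, 1, 0)],
)
def test_tss_is_strand_aware_five_prime_end(strand, start, end, expected):
    g = GeneModel("g", GenomicInterval("chr1", start, end), strand)
    assert tss_of(g) == expected


def test_invalid_strand_is_rejected_naming_the_gene():
    with pytest.raises(ValueError, match="gX"):
        GeneModel("gX", GenomicInterval("chr1", 0, 10), ".")


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((0, 10), (10, 20), False),  # touching is not overlap (half-open)
        ((0, 10), (9, 20), True),  # 1-bp intersection
        ((5, 6), (5, 6), True),
    ],
)
def test_overlap_half_open_semantics(a, b, expected):
    ia = GenomicInterval("chr1", *a)
    ib = GenomicInterval("chr1", *b)
    assert overlaps(ia, ib) is expected
    assert overlaps(ib, ia) is expected


def test_overlap_requires_same_chromosome():
    assert not overlaps(GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10))


@settings(max_examples=1000, derandomize=True)
@given(
    s1=st.integers(0, 200), l1=st.integers(1, 50),
    s2=st.integers(0, 200), l2=st.integers(1, 50),
)
def test_overlap_agrees_with_arithmetic_oracle(s1, l1, s2, l2):
    a = GenomicInterval("chr1", s1, s1 + l1)
    b = GenomicInterval("chr1", s2, s2 + l2)
    oracle = max(s1, s2) < min(s1 + l1, s2 + l2)
    assert overlaps(a, b) == oracle


@pytest.mark.parametrize("bad", [("", 0, 5), ("chr1", -1, 5), ("chr1", 5, 5)])
def test_interval_invariants(bad):
    with pytest.raises(ValueError):
        GenomicInterval(*bad)


def _divergent_genes(minus_tss=5000, plus_tss=5400, chrom="chr1"):
    gm = GeneModel("A", GenomicInterval(chrom, minus_tss - 2000, minus_tss), "-")
    gp = GeneModel("B", GenomicInterval(chrom, plus_tss, plus_tss + 2000), "+")
    return [gm, gp]


def test_derive_h2h_basic_pair():
    pairs = derive_h2h_pairs(_divergent_genes())
    assert len(pairs) == 1
    assert pairs[0].tss_distance == 400
    assert pairs[0].pair_id == "A:B"


def test_derive_h2h_distance_cutoff_is_strict():
    assert derive_h2h_pairs(_divergent_genes(5000, 6000)) == []
    assert len(derive_h2h_pairs(_divergent_genes(5000, 5999))) == 1


def test_derive_h2h_requires_same_chromosome_and_divergence():
    gm, gp = _divergent_genes()
    other = GeneModel("B", GenomicInterval("chr2", 5400, 7400), "+")
    assert derive_h2h_pairs([gm, other]) == []
    # convergent order (plus TSS left of minus TSS) is rejected by default
    conv_minus = GeneModel("C", GenomicInterval("chr1", 5400, 7400), "-")
    conv_plus = GeneModel("D", GenomicInterval("chr1", 3000, 5000), "+")
    assert derive_h2h_pairs([conv_minus, conv_plus]) == []


def test_derive_h2h_duplicate_gene_ids_rejected():
    g = _divergent_genes()
    with pytest.raises(ValueError, match="duplicate"):
        derive_h2h_pairs(g + [g[0]])


def test_derive_h2h_closest_partner_wins_each_gene_once():
    gm = GeneModel("M", GenomicInterval("chr1", 3000, 5000), "-")
    near = GeneModel("N", GenomicInterval("chr1", 5100, 7000), "+")
    far = GeneModel("F", GenomicInterval("chr1", 5700, 7700), "+")
    pairs = derive_h2h_pairs([gm, near, far])
    assert [p.pair_id for p in pairs] == ["M:N"]


def test_derive_h2h_order_independent(small_dataset, rng):
    genes = list(small_dataset.genes)
    reference = derive_h2h_pairs(genes)
    shuffled = list(genes)
    rng.shuffle(shuffled)
    assert derive_h2h_pairs(shuffled) == reference


def test_derive_h2h_recovers_planted_pairs(small_dataset):
    pairs = derive_h2h_pairs(small_dataset.genes)
    assert {p.pair_id for p in pairs} == set(small_dataset.truth.pair_ids)


def test_block_and_promoter_construction():
    pair = make_pair(0, start=1000, l1=4000, gap=400, l2=3600)
    blk = h2h_block(pair)
    assert (blk.start, blk.end) == (1000, 9000)
    prom = bidirectional_promoter(pair)
    assert (prom.start, prom.end) == (5000, 5400)


def test_promoter_contained_in_block_on_planted_pairs(small_dataset):
    for pair in small_dataset.truth.pairs:
        blk = h2h_block(pair)
        assert blk.contains(pair.gene_minus.interval)
        assert blk.contains(pair.gene_plus.interval)
        prom = bidirectional_promoter(pair)
        assert prom is not None and blk.contains(prom)
        assert 0 <= pair.tss_distance < 1000
        assert pair.gene_minus.strand == "-" and pair.gene_plus.strand == "+"


def test_degenerate_promoter_signals_empty():
    gm = GeneModel("M", GenomicInterval("chr1", 3000, 5000), "-")
    gp = GeneModel("P", GenomicInterval("chr1", 5000, 7000), "+")
    pair = H2HPair("M:P", gm, gp, 0)
    assert bidirectional_promoter(pair) is None


@pytest.mark.parametrize(
    "strand,start,end,upstream,expected",
    [
        ("+", 100, 500, 100, (0, 500)),  # clipped at zero
        ("-", 100, 500, 100, (100, 600)),  # upstream of minus gene is rightward
        ("+", 5000, 6000, 100, (4900, 6000)),
    ],
)
def test_background_region_strand_aware(strand, start, end, upstream, expected):
    g = GeneModel("g", GenomicInterval("chr1", start, end), strand)
    region = background_region(g, upstream)
    assert (region.start, region.end) == expected


def test_thresholds_validation():
    with pytest.raises(ValueError):
        Thresholds(max_tss_distance=0)
    with pytest.raises(ValueError):
        Thresholds(overrepresentation_fraction=1.0)
    with pytest.raises(ValueError):
        Thresholds(mr_max=-1)
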