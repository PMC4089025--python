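"""Locus-pair annotation, inter-H2H identification, TF similarity and the
intra/inter enrichment table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from h2hreg.binding import BindingMatrix, annotate_binding
from h2hreg.genome import GeneModel, GenomicInterval, h2h_block, overlaps
from h2hreg.io import LocusPairFile, PeakFile
from h2hreg.spatial import (
    InterH2HPair,
    annotate_loci,
    enrichment_table,
    find_inter_h2h,
    fold_change,
    inter_binding_set,
    interacting_similarity,
    random_inter_null,
    tf_similarity,
)
from .conftest import make_pair, random_interval


def test_annotate_loci_single_and_spanning_blocks():
    p1 = make_pair(1, start=1000)  # block [1000, 5400)
    p2 = make_pair(2, start=8000)  # block [8000, 12400)
    inside = GenomicInterval("chr1", 2000, 2500)
    spanning = GenomicInterval("chr1", 4000, 9000)
    elsewhere = GenomicInterval("chr1", 20000, 21000)
    lp = LocusPairFile(records=[(inside, spanning, None), (elsewhere, inside, None)])
    ann = annotate_loci(lp, [p1, p2])
    assert ann[0] == ({p1.pair_id}, {p1.pair_id, p2.pair_id})
    assert ann[1] == (set(), {p1.pair_id})


def test_annotate_loci_matches_bruteforce(rng):
    pairs = [make_pair(k, chrom=f"chr{1 + k % 2}",
                       start=int(rng.integers(0, 40000))) for k in range(8)]
    blocks = {p.pair_id: h2h_block(p) for p in pairs}
    records = [
        (random_interval(rng, span=50000, max_len=3000),
         random_interval(rng, span=50000, max_len=3000), None)
        for _ in range(50)
    ]
    ann = annotate_loci(LocusPairFile(records=records), pairs)
    for (a, b, _), (got_a, got_b) in zip(records, ann):
        assert got_a == {pid for pid, blk in blocks.items() if overlaps(a, blk)}
        assert got_b == {pid for pid, blk in blocks.items() if overlaps(b, blk)}


def test_find_inter_h2h_self_exclusion_and_dedup():
    ann = [
        ({"P1"}, {"P2"}),
        ({"P1"}, {"P1"}),        # fully annotated, same pair: no inter pair
        ({"P2"}, {"P1"}),        # same unordered pair again
        (set(), {"P1"}),          # not fully annotated
        ({"P1", "P2"}, {"P3"}),  # multi-block locus: two combinations
    ]
    res = find_inter_h2h(ann)
    assert res.fully_annotated == 4
    got = {(ip.pair_a, ip.pair_b): ip.supporting_loci for ip in res.inter_pairs}
    assert got == {("P1", "P2"): (0, 2), ("P1", "P3"): (4,), ("P2", "P3"): (4,)}


def test_find_inter_h2h_order_independent():
    ann = [({"P1"}, {"P2"}), ({"P3"}, {"P1"}), ({"P2"}, {"P1"})]
    res_a = find_inter_h2h(ann)
    res_b = find_inter_h2h(ann[::-1])
    assert {(i.pair_a, i.pair_b) for i in res_a.inter_pairs} == {
        (i.pair_a, i.pair_b) for i in res_b.inter_pairs
    }


def test_find_inter_recovers_planted_contacts(small_dataset):
    ds = small_dataset
    res = find_inter_h2h(annotate_loci(ds.locus_pairs, ds.truth.pairs))
    assert {(i.pair_a, i.pair_b) for i in res.inter_pairs} == set(
        ds.truth.planted_inter
    )


def test_inter_binding_set_union():
    m = BindingMatrix(
        ["A", "B", "C"],
        ["p1", "p2"],
        np.array([[1, 0], [1, 1], [0, 1]]),
    )
    ip = InterH2HPair("p1", "p2", (0,))
    assert inter_binding_set(m, ip) == {"A", "B", "C"}
    empty = BindingMatrix(["A"], ["p1", "p2"], np.zeros((1, 2)))
    assert inter_binding_set(empty, ip) == set()
    with pytest.raises(KeyError):
        inter_binding_set(m, InterH2HPair("p1", "zz", (0,)))


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ({"A", "B"}, {"A", "B"}, 1.0),
        ({"A"}, {"B"}, 0.0),
        ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
        (set(), set(), 0.0),
    ],
)
def test_tf_similarity_examples(a, b, expected):
    assert tf_similarity(a, b) == pytest.approx(expected)


@settings(max_examples=300, derandomize=True)
@given(
    a=st.sets(st.sampled_from("ABCDEFGH")),
    b=st.sets(st.sampled_from("ABCDEFGH")),
)
def test_tf_similarity_properties(a, b):
    s = tf_similarity(a, b)
    assert 0.0 <= s <= 1.0
    assert s == tf_similarity(b, a)
    assert (s == 1.0) == (a == b and bool(a))


def test_random_inter_null_trivial_cases():
    genes = [
        GeneModel(f"g{i}", GenomicInterval("chr1", 1000 * i + 100, 1000 * i + 600),
                  "+")
        for i in range(10)
    ]
    nothing = [PeakFile("TF1", "TF", [])]
    res = random_inter_null(genes, nothing, n=50, seed=3)
    assert res.mean == 0.0 and (res.scores == 0).all()
    everywhere = [PeakFile("TF1", "TF", [GenomicInterval("chr1", 0, 20000)])]
    res = random_inter_null(genes, everywhere, n=50, seed=3)
    assert res.mean == 1.0
    with pytest.raises(ValueError):
        random_inter_null(genes[:1], nothing, n=5, seed=1)
    with pytest.raises(ValueError):
        random_inter_null(genes, nothing, n=0, seed=1)


def test_random_inter_null_reproducible(small_dataset):
    ds = small_dataset
    tf = [p for p in ds.peaksets if p.factor_class == "TF"]
    r1 = random_inter_null(ds.genes, tf, n=100, seed=11)
    r2 = random_inter_null(ds.genes, tf, n=100, seed=11)
    assert (r1.scores == r2.scores).all()


def test_fold_change_arithmetic():
    assert fold_change(0.5, 0.5) == pytest.approx(1.0)
    assert round(fold_change(0.147, 0.40), 2) == 2.72
    assert np.isnan(fold_change(0.0, 0.3))


def test_enrichment_table_union_semantics():
    # F binds p1 (member of every inter pair) but only 1 of 4 intra pairs
    m = BindingMatrix(
        ["F", "G"],
        ["p1", "p2", "p3", "p4"],
        np.array([[1, 0, 0, 0], [1, 1, 1, 1]]),
    )
    inters = [InterH2HPair("p1", "p2", (0,)), InterH2HPair("p1", "p3", (1,))]
    tab = enrichment_table(m, inters).set_index("factor")
    assert tab.loc["F", "intra_fraction"] == pytest.approx(0.25)
    assert tab.loc["F", "inter_fraction"] == pytest.approx(1.0)
    assert tab.loc["F", "fold_change"] == pytest.approx(4.0)
    assert tab.loc["G", "fold_change"] == pytest.approx(1.0)
    # sorted descending by fold change
    assert list(tab.index) == ["F", "G"]


def test_enrichment_table_flags_undefined_last():
    m = BindingMatrix(
        ["DEAD", "G"], ["p1", "p2"], np.array([[0, 0], [1, 1]])
    )
    tab = enrichment_table(m, [InterH2HPair("p1", "p2", (0,))])
    assert list(tab.factor) == ["G", "DEAD"]
    assert np.isnan(tab.fold_change.iloc[-1])
    with pytest.raises(ValueError):
        enrichment_table(m, [])


def test_inter_fraction_dominates_member_fractions(small_dataset):
    ds = small_dataset
    tf = [p for p in ds.peaksets if p.factor_class == "TF"]
    m = annotate_binding(tf, ds.truth.pairs)
    res = find_inter_h2h(annotate_loci(ds.locus_pairs, ds.truth.pairs))
    tab = enrichment_table(m, res.inter_pairs).set_index("factor")
    members = sorted({p for ip in res.inter_pairs for p in (ip.pair_a, ip.pair_b)})
    cols = [m.pairs.index(p) for p in members]
    for i, f in enumerate(m.factors):
        member_fraction = m.values[i, cols].mean()
        assert tab.loc[f, "inter_fraction"] >= member_fraction - 1e-12
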