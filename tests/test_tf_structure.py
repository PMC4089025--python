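"""TF profile correlation, Ward clustering, and the co-occurrence test."""

import math

import numpy as np
import pandas as pd
import pytest

from h2hreg.binding import BindingMatrix
from h2hreg.genome import Thresholds
from h2hreg.tf_structure import (
    cluster_binding_profiles,
    cluster_tfs,
    cooccurrence_edges,
    cooccurrence_pvalue,
    dendrogram_newick,
    tf_profile_correlation,
)


def matrix_from(values, factors=None):
    values = np.asarray(values, dtype=np.int8)
    factors = factors or [f"F{i}" for i in range(values.shape[0])]
    return BindingMatrix(factors, [f"p{j}" for j in range(values.shape[1])], values)


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def test_identical_and_complementary_profiles():
    m = matrix_from([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]])
    corr = tf_profile_correlation(m)
    assert corr.loc["F0", "F1"] == pytest.approx(1.0)
    assert corr.loc["F0", "F2"] == pytest.approx(-1.0)
    assert (np.diag(corr) == 1.0).all()


def test_correlation_matches_direct_formula(rng):
    values = (rng.random((5, 20)) < 0.4).astype(np.int8)
    values[values.std(axis=1) == 0] = 0  # avoid degenerate rows
    values[:, 0] = [1, 0, 1, 0, 1]  # guarantee variance
    m = matrix_from(values)
    corr = tf_profile_correlation(m)
    for i in range(5):
        for j in range(5):
            if values[i].std() and values[j].std():
                assert corr.iloc[i, j] == pytest.approx(
                    pearson_oracle(values[i], values[j]), abs=1e-12
                )


def test_zero_variance_profile_warns_and_zeroes():
    m = matrix_from([[1, 1, 1], [1, 0, 1]])
    with pytest.warns(UserWarning, match="zero-variance"):
        corr = tf_profile_correlation(m)
    assert corr.loc["F0", "F1"] == 0.0
    assert corr.loc["F0", "F0"] == 1.0


def test_cluster_recovers_two_planted_blocks(rng):
    base_a = (rng.random(40) < 0.5).astype(np.int8)
    base_b = 1 - base_a
    values = np.vstack([base_a] * 3 + [base_b] * 3)
    m = matrix_from(values, factors=["A1", "A2", "A3", "B1", "B2", "B3"])
    groups = cluster_tfs(tf_profile_correlation(m), 2)
    assert len({groups[f] for f in ("A1", "A2", "A3")}) == 1
    assert len({groups[f] for f in ("B1", "B2", "B3")}) == 1
    assert groups["A1"] != groups["B1"]


def test_cluster_k_equals_n_and_k_bounds():
    m = matrix_from(np.eye(4, 10, dtype=np.int8))
    corr = tf_profile_correlation(m)
    singletons = cluster_tfs(corr, 4)
    assert sorted(singletons.values()) == [1, 2, 3, 4]
    with pytest.raises(ValueError):
        cluster_tfs(corr, 5)
    with pytest.raises(ValueError):
        cluster_tfs(corr, 0)


def test_cluster_partition_is_order_invariant(rng):
    values = (rng.random((8, 30)) < 0.4).astype(np.int8)
    values[:, 0] = 1
    values[:, 1] = 0
    m = matrix_from(values)
    corr = tf_profile_correlation(m)
    ref = cluster_tfs(corr, 3)
    perm = rng.permutation(8)
    shuffled = corr.iloc[perm, perm]
    got = cluster_tfs(shuffled, 3)

    def partition(groups):
        by = {}
        for f, g in groups.items():
            by.setdefault(g, set()).add(f)
        return {frozenset(v) for v in by.values()}

    assert partition(got) == partition(ref)


def test_zero_variance_rows_excluded_from_profile_clustering():
    values = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 1, 0], [0, 0, 0, 0]],
                      dtype=np.int8)
    m = matrix_from(values, factors=["A", "B", "C", "DEAD"])
    with pytest.warns(UserWarning, match="DEAD"):
        groups = cluster_binding_profiles(m, 2)
    assert "DEAD" not in groups


def exact_binomial_tail(shared, n_a, n_b, n_total):
    p0 = (n_a / n_total) * (n_b / n_total)
    return sum(
        math.comb(n_total, k) * p0**k * (1 - p0) ** (n_total - k)
        for k in range(shared, n_total + 1)
    )


def test_cooccurrence_pvalue_examples():
    assert cooccurrence_pvalue(0, 5, 5, 10) == pytest.approx(1.0)
    # frozen closed-form tail: X ~ Binomial(10, 0.25), P(X >= 5)
    expected = exact_binomial_tail(5, 5, 5, 10)
    assert expected == pytest.approx(0.0781269073486328, abs=1e-12)
    assert cooccurrence_pvalue(5, 5, 5, 10) == pytest.approx(expected, abs=1e-12)


def test_cooccurrence_pvalue_monotone_in_shared():
    prev = 2.0
    for shared in range(0, 13):
        p = cooccurrence_pvalue(shared, 12, 15, 40)
        assert p <= prev + 1e-15
        prev = p


def test_cooccurrence_pvalue_input_validation():
    with pytest.raises(ValueError):
        cooccurrence_pvalue(1, 2, 3, 0)
    with pytest.raises(ValueError):
        cooccurrence_pvalue(5, 4, 6, 10)


def test_cooccurrence_edges_thresholds():
    n = 100
    values = np.zeros((3, n), dtype=np.int8)
    values[0, :20] = 1
    values[1, :20] = 1  # identical to F0: ratio 1.0, tiny p
    values[2, 20:40] = 1  # disjoint from both
    m = matrix_from(values)
    edges = cooccurrence_edges(m, Thresholds())
    assert [(e.tf_a, e.tf_b) for e in edges] == [("F0", "F1")]
    e = edges[0]
    assert e.shared == 20 and e.union == 20 and e.overlap_ratio == 1.0
    assert e.p_value < 0.01


def test_cooccurrence_edges_min_bound_filter():
    n = 100
    values = np.zeros((2, n), dtype=np.int8)
    values[0, :5] = 1
    values[1, :5] = 1  # identical but only 5 bound pairs each
    m = matrix_from(values)
    assert cooccurrence_edges(m, Thresholds()) == []
    relaxed = Thresholds(min_bound_pairs=5)
    assert len(cooccurrence_edges(m, relaxed)) == 1


def test_cooccurrence_edges_overlap_equals_set_oracle(rng, small_dataset):
    from h2hreg.binding import annotate_binding

    tf = [p for p in small_dataset.peaksets if p.factor_class == "TF"]
    m = annotate_binding(tf, small_dataset.truth.pairs)
    edges = cooccurrence_edges(m, Thresholds())
    assert edges, "expected co-occurring planted TFs"
    sets = {f: {p for p, v in zip(m.pairs, m.row(f)) if v} for f in m.factors}
    for e in edges:
        a, b = sets[e.tf_a], sets[e.tf_b]
        assert e.shared == len(a & b)
        assert e.union == len(a | b)
        assert e.overlap_ratio == pytest.approx(len(a & b) / len(a | b))
        assert e.overlap_ratio > 0.6 and e.p_value < 0.01


def test_cooccurrence_edges_invariant_to_factor_order(rng, small_dataset):
    from h2hreg.binding import annotate_binding

    tf = [p for p in small_dataset.peaksets if p.factor_class == "TF"]
    m = annotate_binding(tf, small_dataset.truth.pairs)
    perm = rng.permutation(len(m.factors))
    shuffled = BindingMatrix(
        [m.factors[i] for i in perm], m.pairs, m.values[perm]
    )
    assert cooccurrence_edges(shuffled) == cooccurrence_edges(m)


def test_dendrogram_newick_shape():
    m = matrix_from(np.eye(4, 12, dtype=np.int8))
    nwk = dendrogram_newick(tf_profile_correlation(m))
    assert nwk.endswith(";")
    for name in m.factors:
        assert name in nwk
    assert nwk.count(",") == 3  # n - 1 merges
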