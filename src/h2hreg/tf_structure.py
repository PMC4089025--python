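"""Structure among transcription factors: hierarchical clustering of binding
profiles and the co-occurrence network.

Clustering follows the Pearson-correlation / Ward recipe: the dissimilarity
between two factors is 1 - r between their binary binding profiles, and the
tree is cut into k groups.  Co-occurrence between two factors is judged by a
one-sided binomial test of the shared-pair count against the independence null
(product of marginal binding frequencies), combined with a minimum overlap
(Jaccard) ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import binom

from .binding import BindingMatrix
from .genome import Thresholds

__all__ = [
    "CooccurrenceEdge",
    "tf_profile_correlation",
    "cluster_tfs",
    "cluster_binding_profiles",
    "cooccurrence_pvalue",
    "cooccurrence_edges",
    "linkage_from_correlation",
    "dendrogram_newick",
]


@dataclass(frozen=True)
class CooccurrenceEdge:
    """A co-occurring TF pair: shared / union pair counts, overlap ratio and
    binomial tail p-value."""

    tf_a: str
    tf_b: str
    shared: int
    union: int
    overlap_ratio: float
    p_value: float


def tf_profile_correlation(matrix: BindingMatrix) -> pd.DataFrame:
    """Symmetric Pearson correlation table between factor binding profiles.

    Zero-variance profiles (all-0 or all-1 rows) have undefined correlations;
    a warning is emitted and their off-diagonal entries are set to 0 so the
    derived dissimilarity is maximal-agnostic (d = 1).
    """
    if len(matrix.factors) < 2:
        raise ValueError("need at least two factors to correlate")
    x = matrix.values.astype(float)
    sd = x.std(axis=1)
    degenerate = sd == 0.0
    if degenerate.any():
        names = [f for f, d in zip(matrix.factors, degenerate) if d]
        warnings.warn(
            f"zero-variance binding profiles (correlation undefined, set to 0): {names}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.asarray(r, dtype=float)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=matrix.factors, columns=matrix.factors)


def linkage_from_correlation(corr: pd.DataFrame) -> np.ndarray:
    """Ward linkage on the dissimilarity d = 1 - r."""
    d = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return hierarchy.linkage(squareform(d, checks=False), method="ward")


def cluster_tfs(corr: pd.DataFrame, k: int) -> dict[str, int]:
    """Cut the Ward tree of 1 - r dissimilarities into ``k`` groups.

    Returns a factor -> group-label mapping with labels renumbered 1..k in
    order of first appearance along the factor list, so the partition is
    independent of the input row order.
    """
    n = len(corr.index)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    order = np.argsort(corr.index.to_numpy())
    canon = corr.iloc[order, order]
    labels = hierarchy.fcluster(linkage_from_correlation(canon), t=k,
                                criterion="maxclust")
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for name, lab in zip(canon.index, labels):
        out[name] = relabel.setdefault(int(lab), len(relabel) + 1)
    return {name: out[name] for name in corr.index}


def cluster_binding_profiles(matrix: BindingMatrix, k: int) -> dict[str, int]:
    """Cluster a binding matrix's factors, excluding zero-variance profiles
    (warned) before correlating."""
    keep = [f for f, row in zip(matrix.factors, matrix.values)
            if row.std() > 0.0]
    dropped = sorted(set(matrix.factors) - set(keep))
    if dropped:
        warnings.warn(f"excluding zero-variance profiles from clustering: {dropped}")
    return cluster_tfs(tf_profile_correlation(matrix.subset_factors(keep)), k)


def cooccurrence_pvalue(shared: int, n_a: int, n_b: int, n_total: int) -> float:
    """One-sided upper-tail binomial probability of observing >= ``shared``
    co-bound pairs under the independence null p0 = (n_a/n)(n_b/n)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= shared <= min(n_a, n_b) <= n_total:
        raise ValueError(
            f"need 0 <= shared <= min(n_a, n_b) <= n_total, got "
            f"({shared}, {n_a}, {n_b}, {n_total})"
        )
    p0 = (n_a / n_total) * (n_b / n_total)
    return float(binom.sf(shared - 1, n_total, p0))


def cooccurrence_edges(
    matrix: BindingMatrix, thresholds: Thresholds | None = None,
    bonferroni: bool = False,
) -> list[CooccurrenceEdge]:
    """Test every unordered factor pair where each member binds at least
    ``min_bound_pairs`` pairs; retain edges with p < cooccurrence_p and
    overlap ratio (shared/union) > overlap_ratio_min.

    No multiple-testing correction is applied by default; ``bonferroni=True``
    divides the p cutoff by the number of tested pairs.
    """
    thresholds = thresholds or Thresholds()
    x = matrix.values.astype(bool)
    counts = x.sum(axis=1)
    n_total = len(matrix.pairs)
    eligible = [i for i, c in enumerate(counts) if c >= thresholds.min_bound_pairs]
    n_tests = len(eligible) * (len(eligible) - 1) // 2
    alpha = thresholds.cooccurrence_p / n_tests if (bonferroni and n_tests) else \
        thresholds.cooccurrence_p
    edges: list[CooccurrenceEdge] = []
    for ii, i in enumerate(eligible):
        for j in eligible[ii + 1:]:
            shared = int((x[i] & x[j]).sum())
            union = int((x[i] | x[j]).sum())
            ratio = shared / union if union else 0.0
            p = cooccurrence_pvalue(shared, int(counts[i]), int(counts[j]), n_total)
            if p < alpha and ratio > thresholds.overlap_ratio_min:
                a, b = sorted((matrix.factors[i], matrix.factors[j]))
                edges.append(CooccurrenceEdge(a, b, shared, union, ratio, p))
    edges.sort(key=lambda e: (e.p_value, e.tf_a, e.tf_b))
    return edges


def dendrogram_newick(corr: pd.DataFrame) -> str:
    """Newick text of the Ward tree (branch lengths from merge heights)."""
    z = linkage_from_correlation(corr)
    tree = hierarchy.to_tree(z)
    names = list(corr.index)

    def walk(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = node.get_left(), node.get_right()
        bl_l = node.dist - left.dist
        bl_r = node.dist - right.dist
        return f"({walk(left)}:{bl_l:.6g},{walk(right)}:{bl_r:.6g})"

    return walk(tree) + ";"
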