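"""Mutual-rank co-expression graph and H2H vs non-H2H connectivity.

Gene pairs with mutual rank (MR) at or below the cutoff (20 by default,
inclusive) are co-expressed edges; genes without any co-expressed partner stay
in the graph as singletons.  Connectivity of the H2H gene group is compared to
the remaining genes by a two-sample rank-sum test and by an empirical
resampling null: repeated random draws of |H2H| genes, each scored by its mean
degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.stats import mannwhitneyu

from .genome import Thresholds
from .io import MRRecord

__all__ = ["DegreeComparison", "build_graph", "degree_comparison"]


@dataclass
class DegreeComparison:
    """Degree statistics of H2H vs other genes, rank-test p-value, and the
    resampled mean-degree null distribution with its empirical p-value."""

    h2h_genes: list[str]
    h2h_degrees: np.ndarray
    other_degrees: np.ndarray
    h2h_median: float
    h2h_mean: float
    other_median: float
    other_mean: float
    rank_test_p: float
    resample_means: np.ndarray
    empirical_p: float


def build_graph(
    records: Iterable[MRRecord], all_genes: Sequence[str], mr_max: float = 20.0
) -> nx.Graph:
    """Undirected co-expression graph: edges where MR <= ``mr_max``; every
    gene in ``all_genes`` is a node (singletons included).  Edge genes missing
    from ``all_genes`` are added with a warning."""
    if mr_max <= 0:
        raise ValueError("mr_max must be positive")
    g = nx.Graph()
    g.add_nodes_from(all_genes)
    known = set(all_genes)
    unknown: set[str] = set()
    for r in records:
        if r.mutual_rank > mr_max:
            continue
        for gene in (r.gene_a, r.gene_b):
            if gene not in known:
                unknown.add(gene)
                known.add(gene)
        g.add_edge(r.gene_a, r.gene_b, mutual_rank=r.mutual_rank)
    if unknown:
        warnings.warn(
            f"{len(unknown)} edge gene(s) absent from the gene list were added"
        )
    return g


def degree_comparison(
    graph: nx.Graph, h2h_genes: set[str], thresholds: Thresholds | None = None
) -> DegreeComparison:
    """Compare co-expression degrees of H2H genes against all other genes.

    The rank test is the two-sample Mann-Whitney rank-sum (greater-tail: H2H
    more connected).  The resampling null draws ``n_resamples`` gene sets of
    size |H2H| without replacement and records each draw's mean degree;
    empirical_p is the fraction of draws with mean >= the observed H2H mean.
    """
    thresholds = thresholds or Thresholds()
    missing = h2h_genes - set(graph.nodes)
    if missing:
        warnings.warn(f"{len(missing)} H2H gene(s) not in the graph were dropped")
    h2h = sorted(h2h_genes & set(graph.nodes))
    if not h2h:
        raise ValueError("no H2H genes present in the graph")
    nodes = sorted(graph.nodes)
    deg = dict(graph.degree())
    degrees = np.array([deg[n] for n in nodes], dtype=float)
    is_h2h = np.isin(nodes, h2h)
    h2h_deg = degrees[is_h2h]
    other_deg = degrees[~is_h2h]

    if other_deg.size == 0 or (h2h_deg.size and np.all(degrees == degrees[0])):
        if other_deg.size == 0:
            warnings.warn("H2H set covers every node; rank test skipped")
        rank_p = float("nan")
    else:
        rank_p = float(mannwhitneyu(h2h_deg, other_deg, alternative="greater").pvalue)

    rng = np.random.default_rng(thresholds.rng_seed)
    m, n, r = len(h2h), len(nodes), thresholds.n_resamples
    observed = float(h2h_deg.mean())
    means = np.empty(r, dtype=float)
    chunk = max(1, min(r, int(2e7) // max(n, 1)))
    done = 0
    while done < r:
        c = min(chunk, r - done)
        keys = rng.random((c, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        means[done:done + c] = degrees[idx].mean(axis=1)
        done += c
    empirical_p = float(np.mean(means >= observed))

    return DegreeComparison(
        h2h_genes=h2h,
        h2h_degrees=h2h_deg,
        other_degrees=other_deg,
        h2h_median=float(np.median(h2h_deg)),
        h2h_mean=observed,
        other_median=float(np.median(other_deg)) if other_deg.size else float("nan"),
        other_mean=float(other_deg.mean()) if other_deg.size else float("nan"),
        rank_test_p=rank_p,
        resample_means=means,
        empirical_p=empirical_p,
    )
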