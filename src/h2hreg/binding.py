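"""Binary factor x H2H-pair binding matrix and binding distributions.

A factor (TF, histone mark or DNase) binds an H2H pair when any of its peaks
overlaps the pair's block by at least 1 bp.  The same annotation serves TFs and
epigenetic markers; only the factor class differs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import H2HPair, GenomicInterval, h2h_block
from .io import PeakFile

__all__ = [
    "BindingMatrix",
    "annotate_binding",
    "annotate_intervals",
    "binding_fraction",
    "overrepresented_tfs",
    "bound_pair_count",
    "binding_fraction_table",
]


@dataclass
class BindingMatrix:
    """Binary matrix of factors (rows) x H2H pairs (columns)."""

    factors: list[str]
    pairs: list[str]
    values: np.ndarray  # shape (n_factors, n_pairs), dtype int8, cells in {0,1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.factors), len(self.pairs)):
            raise ValueError("matrix shape inconsistent with factor/pair names")
        if len(set(self.factors)) != len(self.factors):
            raise ValueError("duplicate factor names")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pair ids")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix cells must be 0/1")

    def row(self, factor: str) -> np.ndarray:
        try:
            i = self.factors.index(factor)
        except ValueError:
            raise KeyError(f"unknown factor {factor!r}") from None
        return self.values[i]

    def column(self, pair_id: str) -> np.ndarray:
        try:
            j = self.pairs.index(pair_id)
        except ValueError:
            raise KeyError(f"unknown pair {pair_id!r}") from None
        return self.values[:, j]

    def factors_binding(self, pair_id: str) -> set[str]:
        """The set of factor names binding one pair."""
        col = self.column(pair_id)
        return {f for f, v in zip(self.factors, col) if v}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.factors, columns=self.pairs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BindingMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.int8))

    def subset_factors(self, names: Sequence[str]) -> "BindingMatrix":
        idx = [self.factors.index(n) for n in names]
        return BindingMatrix(list(names), list(self.pairs), self.values[idx])


def _build_trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    return trees


def annotate_intervals(
    peaksets: Sequence[PeakFile], targets: Sequence[GenomicInterval]
) -> BindingMatrix:
    """Binary factor x target-interval matrix: 1 iff any peak of the factor
    overlaps the target (interval-tree indexed; equals the all-vs-all check)."""
    names = [p.factor_name for p in peaksets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate factor names in peak sets")
    trees = _build_trees(targets)
    values = np.zeros((len(peaksets), len(targets)), dtype=np.int8)
    for i, peaks in enumerate(peaksets):
        for peak in peaks.records:
            tree = trees.get(peak.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(peak.start, peak.end):
                values[i, hit.data] = 1
    return BindingMatrix(names, [str(j) for j in range(len(targets))], values)


def annotate_binding(
    peaksets: Sequence[PeakFile], pairs: Sequence[H2HPair]
) -> BindingMatrix:
    """Annotate peak sets to H2H pairs through block overlap.

    cell(factor, pair) = 1 iff any peak of the factor overlaps the pair's
    block (>= 1 bp, half-open).
    """
    blocks = [h2h_block(p) for p in pairs]
    m = annotate_intervals(peaksets, blocks)
    return BindingMatrix(m.factors, [p.pair_id for p in pairs], m.values)


def binding_fraction(matrix: BindingMatrix, factor: str) -> float:
    """Fraction of all pairs in the matrix bound by ``factor``."""
    row = matrix.row(factor)
    if row.size == 0:
        return 0.0
    return float(row.sum()) / row.size


def overrepresented_tfs(matrix: BindingMatrix, threshold: float = 0.45) -> list[str]:
    """Factors binding strictly more than ``threshold`` of pairs, sorted by
    descending binding fraction (name-tiebreak for determinism)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    scored = [(binding_fraction(matrix, f), f) for f in matrix.factors]
    kept = [(fr, f) for fr, f in scored if fr > threshold]
    kept.sort(key=lambda t: (-t[0], t[1]))
    return [f for _, f in kept]


def bound_pair_count(matrix: BindingMatrix) -> int:
    """Number of pairs bound by at least one factor."""
    if matrix.values.size == 0:
        return 0
    return int(matrix.values.any(axis=0).sum())


def binding_fraction_table(matrix: BindingMatrix) -> pd.DataFrame:
    """Per-factor bound counts and fractions (the binding-distribution table)."""
    counts = matrix.values.sum(axis=1)
    n = len(matrix.pairs)
    df = pd.DataFrame(
        {
            "factor": matrix.factors,
            "bound_pairs": counts,
            "fraction": counts / n if n else 0.0,
        }
    )
    return df.sort_values(["fraction", "factor"], ascending=[False, True]).reset_index(
        drop=True
    )
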