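"""Epigenetic-marker (histone / DNase) annotation of H2H blocks and the
chi-square comparison against background genes.

The H2H-side fraction counts pairs whose block overlaps >= 1 peak of the
marker; the background fraction counts genes whose background region (gene
body + 100 bp upstream) overlaps >= 1 peak.  Enrichment is a Pearson
chi-square on the 2x2 observed/not-observed table, 1 df, no continuity
correction by default.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .binding import BindingMatrix, annotate_binding, bound_pair_count
from .genome import GeneModel, H2HPair
from .io import PeakFile
from .spatial import gene_binding_matrix

__all__ = [
    "marker_h2h_fractions",
    "marker_background_fractions",
    "chisq_enrichment",
    "marker_table",
]


def marker_h2h_fractions(
    markers: Sequence[PeakFile], pairs: Sequence[H2HPair]
) -> tuple[pd.DataFrame, int]:
    """Per-marker (count, fraction) of H2H pairs with >= 1 overlapping peak,
    plus the number of pairs carrying at least one of the markers."""
    m = annotate_binding(markers, pairs)
    n = len(pairs)
    counts = m.values.sum(axis=1)
    df = pd.DataFrame(
        {
            "marker": m.factors,
            "h2h_with": counts,
            "h2h_fraction": counts / n if n else 0.0,
        }
    )
    return df, bound_pair_count(m)


def marker_background_fractions(
    markers: Sequence[PeakFile], genes: Sequence[GeneModel], upstream_bp: int = 100
) -> pd.DataFrame:
    """Per-marker fraction of genes whose background region overlaps >= 1 peak."""
    if not genes:
        raise ValueError("background gene set is empty")
    gm = gene_binding_matrix(genes, markers, upstream_bp)
    counts = gm.values.sum(axis=1)
    return pd.DataFrame(
        {
            "marker": gm.factors,
            "bg_with": counts,
            "bg_fraction": counts / len(genes),
        }
    )


def chisq_enrichment(
    h2h_with: int, h2h_total: int, bg_with: int, bg_total: int,
    yates: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square (1 df) on [[h2h_with, h2h_without], [bg_with,
    bg_without]].  Returns (chi2, p); (nan, nan) when any expected cell is 0.
    ``yates=True`` applies the continuity correction."""
    if h2h_total <= 0 or bg_total <= 0:
        raise ValueError("totals must be positive")
    if not 0 <= h2h_with <= h2h_total or not 0 <= bg_with <= bg_total:
        raise ValueError("'with' counts must lie in [0, total]")
    obs = np.array(
        [[h2h_with, h2h_total - h2h_with], [bg_with, bg_total - bg_with]],
        dtype=float,
    )
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if (expected == 0).any():
        return float("nan"), float("nan")
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


def marker_table(
    markers: Sequence[PeakFile],
    pairs: Sequence[H2HPair],
    genes: Sequence[GeneModel],
    upstream_bp: int = 100,
    yates: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Joint report: per-marker H2H count/fraction, background fraction and
    chi-square enrichment; plus the count of pairs with >= 1 marker."""
    h2h_df, with_any = marker_h2h_fractions(markers, pairs)
    bg_df = marker_background_fractions(markers, genes, upstream_bp)
    df = h2h_df.merge(bg_df, on="marker")
    stats = [
        chisq_enrichment(int(r.h2h_with), len(pairs), int(r.bg_with), len(genes),
                         yates=yates)
        for r in df.itertuples(index=False)
    ]
    df["chi2"] = [s[0] for s in stats]
    df["p_value"] = [s[1] for s in stats]
    df = df.sort_values("h2h_fraction", ascending=False).reset_index(drop=True)
    return df, with_any
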