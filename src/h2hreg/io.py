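"""Readers and writers for the tabular formats the pipeline touches.

BED-family inputs are taken verbatim as 0-based half-open; nothing is shifted
on input.  All TSV dialects are tab-separated UTF-8 with ``#`` comment lines
skipped.  Every reader reports malformed input with the offending line number.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import pandas as pd

from .genome import GeneModel, GenomicInterval

__all__ = [
    "PeakFile",
    "LocusPairFile",
    "MRRecord",
    "read_genes",
    "write_genes",
    "read_peaks",
    "write_peaks",
    "read_locus_pairs",
    "write_locus_pairs",
    "read_mr_table",
    "write_mr_table",
    "read_matrix",
    "write_matrix",
    "write_network",
]

FACTOR_CLASSES = ("TF", "histone", "DNase")


@dataclass
class PeakFile:
    """A named peak set (one ChIP-seq/DNase factor) as plain intervals."""

    factor_name: str
    factor_class: str
    records: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.factor_name:
            raise ValueError("factor_name must be non-empty")
        if self.factor_class not in FACTOR_CLASSES:
            raise ValueError(
                f"factor_class must be one of {FACTOR_CLASSES}, got {self.factor_class!r}"
            )


@dataclass
class LocusPairFile:
    """Interacting locus pairs (BEDPE-like), each with an optional score."""

    records: list[tuple[GenomicInterval, GenomicInterval, float | None]] = field(
        default_factory=list
    )


@dataclass(frozen=True)
class MRRecord:
    """One co-expression record: a gene pair with its mutual rank."""

    gene_a: str
    gene_b: str
    mutual_rank: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a!r} not allowed in MR table")
        if self.mutual_rank <= 0:
            raise ValueError("mutual_rank must be positive")


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields), skipping blanks and '#'."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_int(value: str, what: str, path: str | Path, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValueError(
            f"{path}, line {lineno}: non-integer {what} {value!r}"
        ) from None


def _parse_interval(
    fields: Sequence[str], path: str | Path, lineno: int, offset: int = 0
) -> GenomicInterval:
    chrom = fields[offset]
    start = _parse_int(fields[offset + 1], "start", path, lineno)
    end = _parse_int(fields[offset + 2], "end", path, lineno)
    try:
        return GenomicInterval(chrom, start, end)
    except ValueError as exc:
        raise ValueError(f"{path}, line {lineno}: {exc}") from None


def read_genes(path: str | Path, format: str = "BED6") -> list[GeneModel]:
    """Read gene models from BED6 (chrom start end name score strand) or from a
    headered TSV with columns chrom, start, end, gene_id, strand."""
    fmt = format.upper()
    if fmt not in ("BED6", "TSV"):
        raise ValueError(f"unknown gene format {format!r}")
    genes: list[GeneModel] = []
    if fmt == "BED6":
        for lineno, fields in _data_lines(path):
            if len(fields) < 6:
                raise ValueError(
                    f"{path}, line {lineno}: BED6 needs 6 columns, got {len(fields)}"
                )
            iv = _parse_interval(fields, path, lineno)
            name, strand = fields[3], fields[5]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}, line {lineno}: invalid strand {strand!r} for gene {name!r}"
                )
            genes.append(GeneModel(name, iv, strand))
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"chrom", "start", "end", "gene_id", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: TSV gene table missing columns {sorted(missing)}")
        for i, row in enumerate(df.itertuples(index=False), start=2):
            iv = _parse_interval((row.chrom, row.start, row.end), path, i)
            if row.strand not in ("+", "-"):
                raise ValueError(
                    f"{path}, line {i}: invalid strand {row.strand!r} for gene {row.gene_id!r}"
                )
            genes.append(GeneModel(str(row.gene_id), iv, row.strand))
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6 (score column fixed at 0)."""
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_peaks(path: str | Path, factor_name: str, factor_class: str) -> PeakFile:
    """Read a BED3+ peak file; columns beyond the first three are ignored."""
    records: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(
                f"{path}, line {lineno}: BED needs >= 3 columns, got {len(fields)}"
            )
        records.append(_parse_interval(fields, path, lineno))
    return PeakFile(factor_name=factor_name, factor_class=factor_class, records=records)


def write_peaks(peaks: PeakFile, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in peaks.records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_locus_pairs(path: str | Path) -> LocusPairFile:
    """Read BEDPE-like locus pairs: chrom1 start1 end1 chrom2 start2 end2 [score]."""
    records = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ValueError(
                f"{path}, line {lineno}: BEDPE needs >= 6 columns, got {len(fields)}"
            )
        a = _parse_interval(fields, path, lineno, offset=0)
        b = _parse_interval(fields, path, lineno, offset=3)
        score: float | None = None
        if len(fields) >= 7 and fields[6] != ".":
            try:
                score = float(fields[6])
            except ValueError:
                raise ValueError(
                    f"{path}, line {lineno}: non-numeric score {fields[6]!r}"
                ) from None
        records.append((a, b, score))
    return LocusPairFile(records=records)


def write_locus_pairs(pairs: LocusPairFile, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, score in pairs.records:
            s = "." if score is None else repr(score)
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{s}\n"
            )


def read_mr_table(path: str | Path) -> list[MRRecord]:
    """Read a mutual-rank co-expression table (gene_a, gene_b, MR per line).

    The table is symmetric input: duplicate (a,b)/(b,a) records are collapsed
    keeping the smaller mutual rank.
    """
    best: dict[tuple[str, str], float] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(
                f"{path}, line {lineno}: MR table needs 3 columns, got {len(fields)}"
            )
        a, b, raw = fields[0], fields[1], fields[2]
        try:
            mr = float(raw)
        except ValueError:
            raise ValueError(
                f"{path}, line {lineno}: non-numeric mutual rank {raw!r}"
            ) from None
        if a == b:
            raise ValueError(f"{path}, line {lineno}: self-pair {a!r}")
        if mr <= 0:
            raise ValueError(f"{path}, line {lineno}: mutual rank must be positive")
        key = (a, b) if a < b else (b, a)
        if key not in best or mr < best[key]:
            best[key] = mr
    return [MRRecord(a, b, mr) for (a, b), mr in sorted(best.items())]


def write_mr_table(records: Iterable[MRRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"{r.gene_a}\t{r.gene_b}\t{r.mutual_rank:g}\n")


def write_matrix(matrix, path: str | Path, comment: str | None = None) -> None:
    """Write a binary factor x pair matrix as TSV: first column ``factor``,
    one column per pair id, cells 0/1."""
    df = matrix.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index_label="factor")


def read_matrix(path: str | Path):
    """Read a binary matrix written by :func:`write_matrix`; non-binary cells
    are rejected."""
    from .binding import BindingMatrix  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    values = df.to_numpy()
    if values.size and not ((values == 0) | (values == 1)).all():
        bad = values[(values != 0) & (values != 1)].flat[0]
        raise ValueError(f"{path}: matrix cell {bad!r} is not 0/1")
    return BindingMatrix.from_frame(df.astype("int8"))


def write_network(edges, path: str | Path, format: str = "GraphML") -> None:
    """Export a TF co-occurrence edge list as GraphML (attributes preserved)
    or SIF (one ``tf_a cooccurs tf_b`` line per edge)."""
    fmt = format.lower()
    if fmt not in ("graphml", "sif"):
        raise ValueError(f"unknown network format {format!r}")
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for e in edges:
                fh.write(f"{e.tf_a}\tcooccurs\t{e.tf_b}\n")
        return
    g = nx.Graph()
    for e in edges:
        g.add_edge(
            e.tf_a,
            e.tf_b,
            shared=int(e.shared),
            union=int(e.union),
            overlap_ratio=float(e.overlap_ratio),
            p_value=float(e.p_value),
        )
    nx.write_graphml(g, path)
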