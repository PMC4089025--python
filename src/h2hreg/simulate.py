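"""Seeded synthetic datasets with the statistical structure every analysis
stage assumes, plus the planted ground truth used by recovery tests.

The generator emulates the four real input classes of the study — a curated
set of divergent (H2H) gene pairs, per-factor ChIP-seq/DNase peak sets, Hi-C
interacting locus pairs, and a mutual-rank co-expression table:

* ``generate_genome`` lays out H2H pairs (TSS distance 50-999 bp) and
  singleton genes with intergenic gaps of at least 2 kb, so no accidental
  divergent pair arises.  It also plants the latent structure the other
  generators share: a per-block "activity" state, the set of spatially
  interacting H2H pairs, and the (H2H) hub gene set.
* ``generate_peaks`` emits three TF classes.  Bidirectional-class TFs follow
  block activity (high rate on active blocks), which gives their binding
  profiles the within-class correlation that Pearson/Ward clustering detects.
  Spatial-class TFs bind blocks of planted interacting pairs at a boosted
  rate.  Neutral TFs bind independently at base rates.  Epigenetic markers
  (DNase + histones) are mostly activating (block rate boosted over the
  gene-level rate) with two repressive ones.
* ``generate_locus_pairs`` draws the planted fraction of records inside two
  distinct H2H blocks and the rest inside intergenic gaps.
* ``generate_mr_table`` samples co-expression edges with H2H-gene endpoints
  upweighted by ``h2h_degree_boost``.

Each generator owns an independent RNG stream derived from the master seed by
a fixed label, so adding or re-running one generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import GeneModel, GenomicInterval, H2HPair, h2h_block, make_pair_id
from .io import (
    LocusPairFile,
    MRRecord,
    PeakFile,
    write_genes,
    write_locus_pairs,
    write_mr_table,
    write_peaks,
)

__all__ = [
    "TFSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "default_tf_specs",
    "generate_genome",
    "generate_peaks",
    "generate_locus_pairs",
    "generate_mr_table",
    "generate_all",
    "write_dataset",
]

# fixed stream labels: one per generator
_GENOME, _PEAKS, _LOCI, _MR = 11, 22, 33, 44


@dataclass(frozen=True)
class TFSpec:
    """One synthetic TF: its planted class and binding rates.

    ``p_bind_block`` is the per-block binding probability (for the
    bidirectional class this is the rate on *active* blocks; inactive blocks
    fall back to ``p_bind_gene``); ``p_bind_gene`` is the per-gene rate on
    background regions.
    """

    name: str
    tf_class: str  # bidirectional | spatial | neutral
    p_bind_block: float
    p_bind_gene: float

    def __post_init__(self) -> None:
        if self.tf_class not in ("bidirectional", "spatial", "neutral"):
            raise ValueError(f"unknown tf_class {self.tf_class!r}")
        for p in (self.p_bind_block, self.p_bind_gene):
            if not 0.0 <= p <= 1.0:
                raise ValueError("binding probabilities must lie in [0, 1]")


def default_tf_specs(
    n_bidirectional: int = 17, n_spatial: int = 12, n_neutral: int = 16
) -> list[TFSpec]:
    """The default 45-TF panel: 17 bidirectional-promoter TFs, 12 spatial
    TFs, 16 neutral TFs (the study's 17 overrepresented among 45)."""
    specs = [
        TFSpec(f"BID{i:02d}", "bidirectional", 0.85, 0.05)
        for i in range(1, n_bidirectional + 1)
    ]
    specs += [
        TFSpec(f"SPA{i:02d}", "spatial", 0.20, 0.05)
        for i in range(1, n_spatial + 1)
    ]
    specs += [
        TFSpec(f"NEU{i:02d}", "neutral", 0.15, 0.08)
        for i in range(1, n_neutral + 1)
    ]
    return specs


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, sized to the real study by default
    (~1,500 H2H pairs among 20,000 genes, 45 TFs, 10 epigenetic markers,
    500 locus pairs, a co-expression table averaging ~7 neighbours/gene)."""

    seed: int = 0
    n_genes: int = 20000
    h2h_pair_count: int = 1500
    chrom_count: int = 10
    chrom_length: int = 15_000_000
    tf_specs: list[TFSpec] = field(default_factory=default_tf_specs)
    n_histone_markers: int = 10
    active_marker_boost: float = 1.8
    n_locus_pairs: int = 500
    inter_h2h_fraction: float = 0.21
    spatial_share_boost: float = 2.0
    mr_edge_count: int = 150000
    h2h_degree_boost: float = 1.5
    p_block_active: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_genes", "chrom_count", "chrom_length",
                     "n_histone_markers", "n_locus_pairs", "mr_edge_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.h2h_pair_count < 0:
            raise ValueError("h2h_pair_count must be >= 0")
        if 2 * self.h2h_pair_count > self.n_genes:
            raise ValueError("h2h_pair_count * 2 cannot exceed n_genes")
        if not 0.0 <= self.inter_h2h_fraction <= 1.0:
            raise ValueError("inter_h2h_fraction must lie in [0, 1]")
        for name in ("active_marker_boost", "spatial_share_boost",
                     "h2h_degree_boost"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """A desk-scale configuration (same effect sizes, smaller counts)."""
        base = dict(
            seed=seed,
            n_genes=400,
            h2h_pair_count=40,
            chrom_count=2,
            chrom_length=1_500_000,
            tf_specs=default_tf_specs(5, 4, 3),
            n_histone_markers=4,
            n_locus_pairs=40,
            inter_h2h_fraction=0.25,
            mr_edge_count=1500,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset."""

    pairs: list[H2HPair]
    h2h_genes: set[str]
    tf_classes: dict[str, str]
    marker_classes: dict[str, str]
    block_active: dict[str, bool]
    planted_inter: list[tuple[str, str]]
    intergenic: list[GenomicInterval]

    @property
    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list[GeneModel]
    peaksets: list[PeakFile]
    locus_pairs: LocusPairFile
    mr_records: list[MRRecord]
    truth: SyntheticTruth


def _stream(config: SyntheticConfig, label: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, label])


def generate_genome(config: SyntheticConfig) -> tuple[list[GeneModel], SyntheticTruth]:
    """Lay out the synthetic genome and plant the shared latent structure."""
    rng = _stream(config, _GENOME)
    n_pairs = config.h2h_pair_count
    n_single = config.n_genes - 2 * n_pairs
    units = ["P"] * n_pairs + ["S"] * n_single
    rng.shuffle(units)

    genes: list[GeneModel] = []
    pairs: list[H2HPair] = []
    intergenic: list[GenomicInterval] = []
    chrom_idx, cursor = 0, 0
    pair_i, single_i = 0, 0
    for unit in units:
        gap = int(rng.integers(2000, 4001))
        if unit == "P":
            l1 = int(rng.integers(1000, 3001))
            l2 = int(rng.integers(1000, 3001))
            d = int(rng.integers(50, 1000))
            span = gap + l1 + d + l2
        else:
            l1 = int(rng.integers(1000, 3001))
            span = gap + l1
        if cursor + span > config.chrom_length:
            chrom_idx += 1
            cursor = 0
            if chrom_idx >= config.chrom_count:
                raise ValueError(
                    "genes do not fit the genome; increase chrom_length or "
                    "chrom_count, or reduce n_genes"
                )
        chrom = f"chr{chrom_idx + 1}"
        if gap > 0 and cursor > 0:
            intergenic.append(GenomicInterval(chrom, cursor, cursor + gap))
        start = cursor + gap
        if unit == "P":
            pair_i += 1
            gm = GeneModel(f"H2H{pair_i:05d}M",
                           GenomicInterval(chrom, start, start + l1), "-")
            gp = GeneModel(f"H2H{pair_i:05d}P",
                           GenomicInterval(chrom, start + l1 + d,
                                           start + l1 + d + l2), "+")
            genes.extend([gm, gp])
            pairs.append(H2HPair(make_pair_id(gm.gene_id, gp.gene_id), gm, gp, d))
            cursor = gp.interval.end
        else:
            single_i += 1
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel(f"G{single_i:06d}",
                          GenomicInterval(chrom, start, start + l1), strand)
            genes.append(g)
            cursor = g.interval.end

    active = rng.random(len(pairs)) < config.p_block_active
    block_active = {p.pair_id: bool(a) for p, a in zip(pairs, active)}

    # plant the spatially interacting pair set used by loci and spatial TFs
    n_inter = round(config.n_locus_pairs * config.inter_h2h_fraction)
    planted: list[tuple[str, str]] = []
    if n_inter > 0:
        if len(pairs) < 2:
            raise ValueError(
                "need >= 2 H2H pairs to plant interacting inter-H2H pairs"
            )
        capacity = len(pairs) * (len(pairs) - 1) // 2
        if n_inter > capacity:
            raise ValueError("more planted interactions requested than pair combinations")
        chosen: set[tuple[str, str]] = set()
        ids = [p.pair_id for p in pairs]
        while len(chosen) < n_inter:
            i, j = rng.choice(len(ids), size=2, replace=False)
            a, b = sorted((ids[i], ids[j]))
            chosen.add((a, b))
        planted = sorted(chosen)

    truth = SyntheticTruth(
        pairs=pairs,
        h2h_genes={g.gene_id for p in pairs
                   for g in (p.gene_minus, p.gene_plus)},
        tf_classes={s.name: s.tf_class for s in config.tf_specs},
        marker_classes={},
        block_active=block_active,
        planted_inter=planted,
        intergenic=intergenic,
    )
    return genes, truth


def _place_peaks(
    rng: np.random.Generator,
    regions: Sequence[GenomicInterval],
    probs: np.ndarray,
) -> list[GenomicInterval]:
    """Bernoulli-select regions and drop one peak (width 100-400 bp, clipped
    to the region) uniformly inside each selected region."""
    hit = rng.random(len(regions)) < probs
    peaks: list[GenomicInterval] = []
    for region, h in zip(regions, hit):
        if not h:
            continue
        width = min(int(rng.integers(100, 401)), len(region))
        offset = int(rng.integers(0, len(region) - width + 1))
        peaks.append(
            GenomicInterval(region.chrom, region.start + offset,
                            region.start + offset + width)
        )
    return peaks


def generate_peaks(
    config: SyntheticConfig, genes: Sequence[GeneModel], truth: SyntheticTruth
) -> list[PeakFile]:
    """Per-factor peak sets: the configured TF panel followed by the
    epigenetic markers (one DNase set, then histone marks)."""
    rng = _stream(config, _PEAKS)
    names = [s.name for s in config.tf_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate TF names in tf_specs")

    blocks = [h2h_block(p) for p in truth.pairs]
    activity = np.array(
        [truth.block_active[p.pair_id] for p in truth.pairs], dtype=bool
    )
    inter_ids = {pid for ab in truth.planted_inter for pid in ab}
    is_inter = np.array([p.pair_id in inter_ids for p in truth.pairs], dtype=bool)
    from .genome import background_region

    regions = [background_region(g, 100) for g in genes]

    peaksets: list[PeakFile] = []
    for spec in config.tf_specs:
        if spec.tf_class == "bidirectional":
            p_block = np.where(activity, spec.p_bind_block, spec.p_bind_gene)
        elif spec.tf_class == "spatial":
            boosted = min(1.0, spec.p_bind_block * config.spatial_share_boost)
            p_block = np.where(is_inter, boosted, spec.p_bind_block)
        else:
            p_block = np.full(len(blocks), spec.p_bind_block)
        records = _place_peaks(rng, blocks, p_block)
        records += _place_peaks(rng, regions,
                                np.full(len(regions), spec.p_bind_gene))
        records.sort()
        peaksets.append(PeakFile(spec.name, "TF", records))

    # epigenetic markers: DNase + histones, mostly activating, two repressive
    marker_names = ["DNase"] + [f"HIST{i:02d}" for i in
                                range(1, config.n_histone_markers)]
    n_repressive = min(2, max(0, config.n_histone_markers - 2))
    for k, name in enumerate(marker_names):
        repressive = k >= len(marker_names) - n_repressive
        if repressive:
            p_gene, p_block_rate = 0.15, 0.08
            truth.marker_classes[name] = "repressive"
        else:
            p_gene = 0.45
            p_block_rate = min(0.95, p_gene * config.active_marker_boost)
            truth.marker_classes[name] = "active"
        records = _place_peaks(rng, blocks, np.full(len(blocks), p_block_rate))
        records += _place_peaks(rng, regions, np.full(len(regions), p_gene))
        records.sort()
        peaksets.append(
            PeakFile(name, "DNase" if name == "DNase" else "histone", records)
        )
    return peaksets


def _interval_inside(
    rng: np.random.Generator, region: GenomicInterval,
    min_width: int = 500, max_width: int = 1500,
) -> GenomicInterval:
    width = min(int(rng.integers(min_width, max_width + 1)), len(region))
    offset = int(rng.integers(0, len(region) - width + 1))
    return GenomicInterval(region.chrom, region.start + offset,
                           region.start + offset + width)


def generate_locus_pairs(
    config: SyntheticConfig, truth: SyntheticTruth
) -> LocusPairFile:
    """Interacting locus pairs: the planted fraction joins two distinct H2H
    blocks (loci drawn inside the blocks); the rest joins intergenic gaps."""
    rng = _stream(config, _LOCI)
    n_inter = len(truth.planted_inter)
    if round(config.n_locus_pairs * config.inter_h2h_fraction) > 0 and \
            len(truth.pairs) < 2:
        raise ValueError("need >= 2 H2H pairs for a nonzero inter_h2h_fraction")
    blocks = {p.pair_id: h2h_block(p) for p in truth.pairs}
    records: list[tuple[GenomicInterval, GenomicInterval, float | None]] = []
    for a, b in truth.planted_inter:
        records.append(
            (_interval_inside(rng, blocks[a]), _interval_inside(rng, blocks[b]),
             None)
        )
    gaps = [g for g in truth.intergenic if len(g) >= 600]
    if len(gaps) < 2 and config.n_locus_pairs > n_inter:
        raise ValueError("not enough intergenic space for background locus pairs")
    for _ in range(config.n_locus_pairs - n_inter):
        i, j = rng.choice(len(gaps), size=2, replace=False)
        records.append(
            (_interval_inside(rng, gaps[i]), _interval_inside(rng, gaps[j]), None)
        )
    order = rng.permutation(len(records))
    return LocusPairFile(records=[records[i] for i in order])


def generate_mr_table(
    config: SyntheticConfig, genes: Sequence[GeneModel], truth: SyntheticTruth
) -> list[MRRecord]:
    """Mutual-rank co-expression edges, H2H endpoints upweighted by
    ``h2h_degree_boost``; MR ~ Uniform(1, 40) so the MR <= 20 cut keeps about
    half of the records."""
    rng = _stream(config, _MR)
    ids = [g.gene_id for g in genes]
    n = len(ids)
    capacity = n * (n - 1) // 2
    if config.mr_edge_count > capacity:
        raise ValueError(
            f"mr_edge_count {config.mr_edge_count} exceeds simple-graph "
            f"capacity {capacity}"
        )
    w = np.array(
        [config.h2h_degree_boost if g in truth.h2h_genes else 1.0 for g in ids]
    )
    p = w / w.sum()
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < config.mr_edge_count:
        need = config.mr_edge_count - len(chosen)
        draw = rng.choice(n, size=(int(need * 1.3) + 8, 2), p=p)
        for i, j in draw:
            if i == j:
                continue
            key = (i, j) if i < j else (j, i)
            chosen.add(key)
            if len(chosen) == config.mr_edge_count:
                break
    edges = sorted(chosen)
    mr = rng.uniform(1.0, 40.0, size=len(edges))
    return [
        MRRecord(ids[i], ids[j], round(float(m), 3))
        for (i, j), m in zip(edges, mr)
    ]


def generate_all(config: SyntheticConfig) -> SyntheticDataset:
    """Run every generator in its fixed order and bundle the dataset."""
    genes, truth = generate_genome(config)
    locus_pairs = generate_locus_pairs(config, truth)
    peaksets = generate_peaks(config, genes, truth)
    mr_records = generate_mr_table(config, genes, truth)
    return SyntheticDataset(config, genes, peaksets, locus_pairs, mr_records, truth)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the pipeline's own input formats plus a truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genes"] = outdir / "genes.bed"
    write_genes(dataset.genes, paths["genes"])

    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    manifest_lines = ["factor\tclass\tpath"]
    for pf in dataset.peaksets:
        p = peak_dir / f"{pf.factor_name}.bed"
        write_peaks(pf, p)
        manifest_lines.append(f"{pf.factor_name}\t{pf.factor_class}\tpeaks/{pf.factor_name}.bed")
    paths["peaks_manifest"] = outdir / "peaks_manifest.tsv"
    paths["peaks_manifest"].write_text("\n".join(manifest_lines) + "\n",
                                       encoding="utf-8")

    paths["locus_pairs"] = outdir / "locus_pairs.bedpe"
    write_locus_pairs(dataset.locus_pairs, paths["locus_pairs"])

    paths["mr_table"] = outdir / "mr_table.tsv"
    write_mr_table(dataset.mr_records, paths["mr_table"])

    truth = dataset.truth
    lines = ["kind\tkey\tvalue"]
    for p in truth.pairs:
        lines.append(f"h2h_pair\t{p.pair_id}\t{p.tss_distance}")
    for name, cls in truth.tf_classes.items():
        lines.append(f"tf_class\t{name}\t{cls}")
    for name, cls in truth.marker_classes.items():
        lines.append(f"marker_class\t{name}\t{cls}")
    for pid, act in truth.block_active.items():
        lines.append(f"block_active\t{pid}\t{int(act)}")
    for a, b in truth.planted_inter:
        lines.append(f"planted_inter\t{a}\t{b}")
    paths["truth"] = outdir / "truth.tsv"
    paths["truth"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths
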