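"""Stage orchestration: run each analysis over files on disk and emit the
report tables.

Stages mirror the study's figures and tables: binding matrix and per-TF
binding distribution; TF clustering (dendrogram + groups); co-occurrence
network; inter-H2H pairs with TF-similarity summary and the intra/inter
fold-change enrichment table; epigenetic-marker proportions with chi-square;
and the co-expression degree comparison.  Every report table carries a header
line naming the thresholds used, and ``run_all`` writes a machine-readable
run manifest.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding as tb
from . import coexpression as cx
from . import markers as mk
from . import spatial as sp
from . import tf_structure as ts
from .genome import GeneModel, H2HPair, Thresholds, derive_h2h_pairs
from .io import (
    PeakFile,
    read_genes,
    read_locus_pairs,
    read_matrix,
    read_mr_table,
    read_peaks,
    write_matrix,
    write_network,
)
from .simulate import SyntheticConfig, generate_all, write_dataset

__all__ = ["RunConfig", "run_simulate", "run_all",
           "stage_annotate", "stage_cluster", "stage_coocnet",
           "stage_spatial", "stage_markers", "stage_coexpress"]

log = logging.getLogger("h2hreg")


@dataclass
class RunConfig:
    """Input locations, output directory and thresholds for one run."""

    genes: Path
    peaks_manifest: Path
    outdir: Path
    locus_pairs: Path | None = None
    mr_table: Path | None = None
    thresholds: Thresholds = dataclasses.field(default_factory=Thresholds)
    gene_format: str = "BED6"
    n_cluster_groups: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        base = path.parent

        def resolve(key):
            return (base / raw[key]).resolve() if raw.get(key) else None

        thresholds = Thresholds(**raw.get("thresholds", {}))
        rc = cls(
            genes=resolve("genes"),
            peaks_manifest=resolve("peaks_manifest"),
            outdir=(base / raw.get("outdir", "report")).resolve(),
            locus_pairs=resolve("locus_pairs"),
            mr_table=resolve("mr_table"),
            thresholds=thresholds,
            gene_format=raw.get("gene_format", "BED6"),
            n_cluster_groups=int(raw.get("n_cluster_groups", 2)),
        )
        if rc.genes is None or rc.peaks_manifest is None:
            raise ValueError(f"{path}: config must name 'genes' and 'peaks_manifest'")
        return rc


def _threshold_header(t: Thresholds) -> str:
    fields = ", ".join(
        f"{f.name}={getattr(t, f.name)}" for f in dataclasses.fields(t)
    )
    return f"# thresholds: {fields}"


def _write_table(df: pd.DataFrame, path: Path, thresholds: Thresholds) -> Path:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_threshold_header(thresholds) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def load_peaksets(manifest: str | Path) -> list[PeakFile]:
    """Load every peak set named in a manifest TSV (factor, class, path
    relative to the manifest)."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest, sep="\t")
    required = {"factor", "class", "path"}
    if not required <= set(df.columns):
        raise ValueError(f"{manifest}: manifest needs columns {sorted(required)}")
    return [
        read_peaks(manifest.parent / row["path"], row["factor"], row["class"])
        for _, row in df.iterrows()
    ]


def _load_inputs(rc: RunConfig) -> tuple[list[GeneModel], list[H2HPair],
                                         list[PeakFile], list[PeakFile]]:
    genes = read_genes(rc.genes, format=rc.gene_format)
    pairs = derive_h2h_pairs(genes, rc.thresholds)
    peaksets = load_peaksets(rc.peaks_manifest)
    tf_sets = [p for p in peaksets if p.factor_class == "TF"]
    marker_sets = [p for p in peaksets if p.factor_class in ("histone", "DNase")]
    return genes, pairs, tf_sets, marker_sets


def run_simulate(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the synthetic dataset, write it, and drop a ready-to-run
    pipeline config next to it."""
    outdir = Path(outdir)
    dataset = generate_all(config)
    paths = write_dataset(dataset, outdir)
    run_cfg = {
        "genes": "genes.bed",
        "peaks_manifest": "peaks_manifest.tsv",
        "locus_pairs": "locus_pairs.bedpe",
        "mr_table": "mr_table.tsv",
        "outdir": "report",
        "thresholds": {"rng_seed": config.seed},
    }
    cfg_path = outdir / "run_config.yaml"
    cfg_path.write_text(yaml.safe_dump(run_cfg), encoding="utf-8")
    paths["run_config"] = cfg_path
    log.info("simulated dataset with %d genes, %d H2H pairs",
             len(dataset.genes), len(dataset.truth.pairs))
    return paths


def stage_annotate(rc: RunConfig) -> tuple[list[H2HPair], tb.BindingMatrix]:
    """Derive H2H pairs, annotate TF binding, write the binary matrix and the
    binding-distribution table."""
    rc.outdir.mkdir(parents=True, exist_ok=True)
    _, pairs, tf_sets, _ = _load_inputs(rc)
    matrix = tb.annotate_binding(tf_sets, pairs)
    write_matrix(matrix, rc.outdir / "binding_matrix.tsv",
                 comment=_threshold_header(rc.thresholds).lstrip("# "))
    frac = tb.binding_fraction_table(matrix)
    _write_table(frac, rc.outdir / "binding_fractions.tsv", rc.thresholds)
    over = tb.overrepresented_tfs(matrix,
                                  rc.thresholds.overrepresentation_fraction)
    _write_table(pd.DataFrame({"factor": over}),
                 rc.outdir / "overrepresented_tfs.tsv", rc.thresholds)
    log.info("annotate: %d TFs x %d pairs, %d pairs bound, %d overrepresented",
             len(matrix.factors), len(matrix.pairs),
             tb.bound_pair_count(matrix), len(over))
    return pairs, matrix


def _matrix_or_load(rc: RunConfig, matrix: tb.BindingMatrix | None) -> tb.BindingMatrix:
    if matrix is not None:
        return matrix
    path = rc.outdir / "binding_matrix.tsv"
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found; run the annotate stage first"
        )
    return read_matrix(path)


def stage_cluster(rc: RunConfig, matrix: tb.BindingMatrix | None = None) -> dict[str, int]:
    """Cluster TF binding profiles (Pearson/Ward) and export the dendrogram
    and the group assignment."""
    matrix = _matrix_or_load(rc, matrix)
    corr = ts.tf_profile_correlation(matrix)
    groups = ts.cluster_tfs(corr, rc.n_cluster_groups)
    (rc.outdir / "dendrogram.nwk").write_text(
        ts.dendrogram_newick(corr) + "\n", encoding="utf-8"
    )
    _write_table(
        pd.DataFrame({"factor": list(groups), "group": list(groups.values())}),
        rc.outdir / "tf_groups.tsv", rc.thresholds,
    )
    return groups


def stage_coocnet(rc: RunConfig, matrix: tb.BindingMatrix | None = None):
    """Build and export the TF co-occurrence network."""
    matrix = _matrix_or_load(rc, matrix)
    edges = ts.cooccurrence_edges(matrix, rc.thresholds)
    df = pd.DataFrame(
        [dataclasses.asdict(e) for e in edges],
        columns=["tf_a", "tf_b", "shared", "union", "overlap_ratio", "p_value"],
    )
    _write_table(df, rc.outdir / "cooccurrence_edges.tsv", rc.thresholds)
    write_network(edges, rc.outdir / "cooccurrence_network.graphml", "GraphML")
    write_network(edges, rc.outdir / "cooccurrence_network.sif", "SIF")
    log.info("coocnet: %d edges", len(edges))
    return edges


def stage_spatial(
    rc: RunConfig,
    pairs: list[H2HPair] | None = None,
    matrix: tb.BindingMatrix | None = None,
):
    """Map locus pairs to blocks, list inter-H2H pairs, summarize TF
    similarity against the random-pair null, and write the enrichment table."""
    if rc.locus_pairs is None:
        raise ValueError("spatial stage requires a locus_pairs input")
    genes, derived_pairs, tf_sets, _ = _load_inputs(rc)
    pairs = pairs if pairs is not None else derived_pairs
    matrix = _matrix_or_load(rc, matrix)
    locus_pairs = read_locus_pairs(rc.locus_pairs)

    ann = sp.annotate_loci(locus_pairs, pairs)
    result = sp.find_inter_h2h(ann)
    inter_df = pd.DataFrame(
        [
            {"pair_a": ip.pair_a, "pair_b": ip.pair_b,
             "n_supporting_loci": len(ip.supporting_loci),
             "supporting_loci": ",".join(map(str, ip.supporting_loci))}
            for ip in result.inter_pairs
        ],
        columns=["pair_a", "pair_b", "n_supporting_loci", "supporting_loci"],
    )
    _write_table(inter_df, rc.outdir / "inter_h2h_pairs.tsv", rc.thresholds)

    interacting = sp.interacting_similarity(matrix, result.inter_pairs)
    random = sp.random_inter_null(
        genes, tf_sets, rc.thresholds.n_random_pairs,
        seed=rc.thresholds.rng_seed, upstream_bp=rc.thresholds.upstream_bp,
    )
    sim_df = pd.DataFrame(
        [
            {"group": s.group, "n": len(s.scores), "mean_similarity": s.mean}
            for s in (interacting, random)
        ]
    )
    _write_table(sim_df, rc.outdir / "tf_similarity.tsv", rc.thresholds)

    if result.inter_pairs:
        enr = sp.enrichment_table(matrix, result.inter_pairs)
    else:
        enr = pd.DataFrame(
            columns=["factor", "intra_fraction", "inter_fraction", "fold_change",
                     "intra_pct", "inter_pct", "fold_change_display"]
        )
    _write_table(enr, rc.outdir / "enrichment_table.tsv", rc.thresholds)
    log.info("spatial: %d fully annotated records, %d inter-H2H pairs, "
             "similarity %.3f (interacting) vs %.3f (random)",
             result.fully_annotated, len(result.inter_pairs),
             interacting.mean, random.mean)
    return result, interacting, random, enr


def stage_markers(rc: RunConfig, pairs: list[H2HPair] | None = None):
    """Epigenetic-marker proportions on H2H pairs vs background genes."""
    genes, derived_pairs, _, marker_sets = _load_inputs(rc)
    if not marker_sets:
        raise ValueError("markers stage requires histone/DNase peak sets")
    pairs = pairs if pairs is not None else derived_pairs
    table, with_any = mk.marker_table(
        marker_sets, pairs, genes, upstream_bp=rc.thresholds.upstream_bp
    )
    _write_table(table, rc.outdir / "marker_table.tsv", rc.thresholds)
    log.info("markers: %d/%d pairs carry >= 1 marker", with_any, len(pairs))
    return table, with_any


def stage_coexpress(rc: RunConfig):
    """Build the MR-thresholded co-expression graph and compare H2H vs
    non-H2H connectivity."""
    if rc.mr_table is None:
        raise ValueError("coexpress stage requires an mr_table input")
    genes = read_genes(rc.genes, format=rc.gene_format)
    pairs = derive_h2h_pairs(genes, rc.thresholds)
    h2h_genes = {g.gene_id for p in pairs for g in (p.gene_minus, p.gene_plus)}
    records = read_mr_table(rc.mr_table)
    graph = cx.build_graph(records, [g.gene_id for g in genes],
                           rc.thresholds.mr_max)
    comp = cx.degree_comparison(graph, h2h_genes, rc.thresholds)

    deg = dict(graph.degree())
    per_gene = pd.DataFrame(
        {
            "gene": list(deg),
            "degree": list(deg.values()),
            "h2h": [g in h2h_genes for g in deg],
        }
    ).sort_values("gene")
    _write_table(per_gene, rc.outdir / "degree_table.tsv", rc.thresholds)

    summary = pd.DataFrame(
        [
            {"group": "h2h", "n": len(comp.h2h_degrees),
             "median": comp.h2h_median, "mean": comp.h2h_mean},
            {"group": "other", "n": len(comp.other_degrees),
             "median": comp.other_median, "mean": comp.other_mean},
        ]
    )
    summary["rank_test_p"] = comp.rank_test_p
    summary["empirical_p"] = comp.empirical_p
    _write_table(summary, rc.outdir / "degree_summary.tsv", rc.thresholds)
    _write_table(pd.DataFrame({"resample_mean": comp.resample_means}),
                 rc.outdir / "resample_means.tsv", rc.thresholds)

    # binned degree histogram, percentage of genes per group
    edges = [0, 1, 2, 3, 4, 5, 7, 10, 15, 20, 30, 50, np.inf]
    rows = []
    for name, arr in (("h2h", comp.h2h_degrees), ("other", comp.other_degrees)):
        if arr.size == 0:
            continue
        hist, _ = np.histogram(arr, bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], hist):
            rows.append({"group": name, "degree_min": lo, "degree_max": hi,
                         "percent": 100.0 * c / arr.size})
    _write_table(pd.DataFrame(rows), rc.outdir / "degree_histogram.tsv",
                 rc.thresholds)
    log.info("coexpress: median degree %.1f (H2H) vs %.1f (other), "
             "empirical p = %.4g", comp.h2h_median, comp.other_median,
             comp.empirical_p)
    return comp


_STAGES = ("annotate", "cluster", "coocnet", "spatial", "markers", "coexpress")


def run_all(rc: RunConfig) -> dict[str, object]:
    """Run every stage in order; on failure, leave partial outputs plus a
    FAILED marker naming the stage, and re-raise."""
    rc.outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    current = ""
    try:
        current = "annotate"
        pairs, matrix = stage_annotate(rc)
        results["pairs"], results["matrix"] = pairs, matrix
        current = "cluster"
        results["groups"] = stage_cluster(rc, matrix)
        current = "coocnet"
        results["edges"] = stage_coocnet(rc, matrix)
        if rc.locus_pairs is not None:
            current = "spatial"
            results["spatial"] = stage_spatial(rc, pairs, matrix)
        if rc.mr_table is not None:
            current = "coexpress"
            results["coexpress"] = stage_coexpress(rc)
        current = "markers"
        results["markers"] = stage_markers(rc, pairs)
    except Exception as exc:
        (rc.outdir / "FAILED").write_text(
            f"stage {current} failed: {exc}\n", encoding="utf-8"
        )
        raise RuntimeError(f"stage {current!r} failed: {exc}") from exc

    manifest = {
        "package": "h2hreg",
        "stages": list(_STAGES),
        "thresholds": dataclasses.asdict(rc.thresholds),
        "inputs": {
            "genes": str(rc.genes),
            "peaks_manifest": str(rc.peaks_manifest),
            "locus_pairs": str(rc.locus_pairs) if rc.locus_pairs else None,
            "mr_table": str(rc.mr_table) if rc.mr_table else None,
        },
    }
    (rc.outdir / "run_manifest.yaml").write_text(
        yaml.safe_dump(manifest), encoding="utf-8"
    )
    return results
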