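#!/usr/bin/env python
"""Cluster TF binding profiles (Pearson correlation + Ward, cut at k=2) and
build the TF co-occurrence network (binomial p < 0.01, overlap ratio > 0.6,
each TF binding >= 10 pairs)."""

from collections import Counter
from pathlib import Path

from h2hreg.pipeline import RunConfig, stage_cluster, stage_coocnet

ROOT = Path(__file__).resolve().parents[1]
rc = RunConfig.from_yaml(ROOT / "results" / "data" / "run_config.yaml")
rc.outdir = ROOT / "results" / "report"

groups = stage_cluster(rc)
sizes = Counter(groups.values())
print(f"TFs clustered into {len(sizes)} groups with sizes "
      f"{sorted(sizes.values(), reverse=True)}")

edges = stage_coocnet(rc)
print(f"co-occurrence network: {len(edges)} edges among "
      f"{len({n for e in edges for n in (e.tf_a, e.tf_b)})} TFs")
print(f"outputs: dendrogram.nwk, tf_groups.tsv, cooccurrence_network.graphml/.sif")
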