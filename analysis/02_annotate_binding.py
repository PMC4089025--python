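#!/usr/bin/env python
"""Annotate TF peaks to H2H blocks and characterize the binding distribution:
how many pairs are bound at all, and which TFs are overrepresented (binding
more than 45% of pairs)."""

from pathlib import Path

from h2hreg.binding import binding_fraction_table, bound_pair_count, overrepresented_tfs
from h2hreg.pipeline import RunConfig, stage_annotate

ROOT = Path(__file__).resolve().parents[1]
rc = RunConfig.from_yaml(ROOT / "results" / "data" / "run_config.yaml")
rc.outdir = ROOT / "results" / "report"

pairs, matrix = stage_annotate(rc)
over = overrepresented_tfs(matrix, rc.thresholds.overrepresentation_fraction)
table = binding_fraction_table(matrix)
print(f"{len(pairs)} H2H pairs; {bound_pair_count(matrix)} bound by >= 1 of "
      f"{len(matrix.factors)} TFs")
print(f"{len(over)} overrepresented TFs (>45% of pairs): {', '.join(over)}")
print(f"tables: {rc.outdir}/binding_matrix.tsv, binding_fractions.tsv")
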