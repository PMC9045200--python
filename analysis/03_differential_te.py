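#!/usr/bin/env python
"""Differential translation-efficiency analysis of the count matrices.

CPM normalization on assigned counts, low-expression filtering (>= 1 CPM in
at least one condition x assay cell), signed fold changes, per-gene TE, the
covariance-corrected SD of each ratio, Welch tests on log2 CPM with BH-FDR,
and up/down classification at |fold| >= 2, q < 0.05. Also writes the
fold-correlation scatter and the TE volcano coordinates, and prints the
affected genes with their planted truth for comparison.

Requires: results/run/counts_*.tsv (from 02_map_and_count.py)
Output:   results/run/diffte.tsv, summary.json, scatter.tsv, volcano_te.tsv
"""

import json
from pathlib import Path

import pandas as pd

from ribotide.pipeline import PipelineConfig, stage_differential
from ribotide.quantify import CountMatrix
from ribotide.simulate import GroundTruth

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    manifest = pd.read_csv(OUTDIR / "sim" / "manifest.tsv", sep="\t",
                           index_col="sample_id")
    matrices = {}
    for key, name in (("rpf", "RPF"), ("rna", "RNA")):
        counts = pd.read_csv(OUTDIR / f"counts_{key}.tsv", sep="\t",
                             index_col=0)
        samples = manifest.loc[list(counts.columns),
                               ["condition", "replicate"]]
        matrices[key] = CountMatrix(name, counts, samples)
    config = PipelineConfig(outdir=OUTDIR)
    _, _, stats_table, summary = stage_differential(config, matrices, OUTDIR)

    print(json.dumps(summary, indent=2, sort_keys=True))
    truth = GroundTruth.from_tsv(OUTDIR / "sim" / "ground_truth.tsv")
    affected = stats_table[
        (stats_table["class_te"] != "unchanged")
        | (stats_table["class_mrna"] != "unchanged")
    ]
    cols = ["fc_mrna", "sd_fc_mrna", "fc_rpf", "sd_fc_rpf",
            "fc_te", "sd_fc_te", "q_te"]
    table = affected[cols].round(2)
    table["planted_mrna"] = truth.table.loc[table.index, "mrna_fold"]
    table["planted_te"] = truth.table.loc[table.index, "te_fold"]
    print("\naffected genes (estimated vs planted):")
    print(table.to_string())


if __name__ == "__main__":
    main()
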