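#!/usr/bin/env python
"""Start-region depletion and codon-pause analysis of the A-site coverage.

Reads the per-condition A-site bedGraph tracks back in, computes per-gene
start(5 codons)/body density ratios and the mutant/wild-type depletion
score, then the per-codon pooled occupancy scores (edge codons excluded)
and the mutant/wild-type pause ratio per codon, and prints the genes with
the strongest start-codon depletion plus the top paused codons.

Requires: results/run/rpf_asite_*.bedgraph (from 02_map_and_count.py)
Output:   results/run/start_stats.tsv, codon_occupancy.tsv
"""

from pathlib import Path

from ribotide.io import CoverageTrack, read_annotation, read_bedgraph_into, \
    read_fasta
from ribotide.pipeline import PipelineConfig, stage_positional

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    simdir = OUTDIR / "sim"
    genome = read_fasta(simdir / "genome.fasta")[0]
    annotations = read_annotation(simdir / "annotation.gff3")
    tracks = {}
    for cond in ("WT", "MUT"):
        track = CoverageTrack({genome.chrom_id: len(genome)})
        read_bedgraph_into(track, OUTDIR / f"rpf_asite_{cond}_plus.bedgraph",
                           "+")
        read_bedgraph_into(track, OUTDIR / f"rpf_asite_{cond}_minus.bedgraph",
                           "-")
        tracks[cond] = track
    config = PipelineConfig(outdir=OUTDIR)
    result = stage_positional(config, genome, annotations, tracks, OUTDIR)

    start = result["start_stats"].sort_values("depletion_score")
    print("strongest start-region depletion (MUT/WT start:body ratio):")
    print(start[["start_ratio_wt", "start_ratio_mut",
                 "depletion_score"]].head(5).round(3).to_string())
    pause = result["pause_table"].sort_values("pause_ratio", ascending=False)
    print("\nmost mutant-paused codons (normalized occupancy MUT/WT):")
    print(pause[["mean_score_wt", "mean_score_mut",
                 "pause_ratio"]].head(5).round(3).to_string())


if __name__ == "__main__":
    main()
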