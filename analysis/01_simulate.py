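#!/usr/bin/env python
"""Generate the synthetic two-condition ribosome-profiling dataset.

Builds the toy operon genome, plants the default effect panel (a strong
translationally attenuated gene with start-codon depletion, a milder TE-down
gene, an mRNA-up gene, a well-expressed pause exemplar, and a mutant-wide
2x AGA dwell factor), and writes 12 seeded FASTQ libraries (2 conditions x
3 replicates x {RPF, RNA}) plus the ground-truth table.

Output: results/run/sim/
"""

from pathlib import Path

from ribotide.pipeline import PipelineConfig, stage_simulate
from ribotide.simulate import SimulationConfig, panel_gene_ids

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "run"
SEED = 42


def main() -> None:
    config = PipelineConfig(outdir=OUTDIR, sim=SimulationConfig(seed=SEED))
    genome, annotations, truth, manifest = stage_simulate(config)
    roles = panel_gene_ids(annotations)
    print(f"chromosome: {len(genome):,} nt, {len(annotations)} CDS features")
    print(f"samples: {len(manifest)} "
          f"({manifest['n_reads'].sum():,} reads total)")
    print("planted panel:")
    for role, gid in roles.items():
        row = truth.table.loc[gid]
        print(f"  {role:15s} {gid}: mrna_fold={row['mrna_fold']:+.1f} "
              f"te_fold={row['te_fold']:+.1f} "
              f"start_depletion={row['start_depletion']:.1f}")


if __name__ == "__main__":
    main()
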