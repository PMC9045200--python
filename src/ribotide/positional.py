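"""Start-region occupancy and codon-level pause analysis.

Start-region statistics compare the mean A-site density of a gene's first
``window`` codons with the density over the gene body (codons window+1 ..
L-window). The per-gene depletion score is the mutant start/body ratio
divided by the wild-type one, so it is invariant to library size and to the
gene's overall expression change; scores well below 1 reproduce the reduced
ribosome engagement at start codons seen for translationally attenuated
genes in the mutant.

Codon pause scores normalize each codon's A-site density by its gene's mean
density and pool the normalized scores by codon identity across genes
(excluding edge codons to avoid initiation/termination artifacts). The
mutant/wild-type pause ratio per codon then exposes codons - e.g. the rare
arginine codon AGA - that the mutant ribosome dwells on longer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CoverageTrack, GeneAnnotation, GenomeSequence, revcomp

START_WINDOW_CODONS = 5
EDGE_EXCLUDE_CODONS = 5


def _per_codon_counts(track: CoverageTrack, ann: GeneAnnotation
                      ) -> np.ndarray:
    """A-site counts per codon (sum over the codon's three nucleotides)."""
    vec = track.get(ann.chrom_id, ann.strand)[ann.start - 1 : ann.end]
    if ann.strand == "-":
        vec = vec[::-1]
    return vec.reshape(-1, 3).sum(axis=1)


@dataclass(frozen=True)
class StartRegionStats:
    gene_id: str
    start_density_wt: float
    start_density_mut: float
    body_density_wt: float
    body_density_mut: float
    start_ratio_wt: float
    start_ratio_mut: float
    depletion_score: float


def start_region_stats(
    coverage_wt: CoverageTrack,
    coverage_mut: CoverageTrack,
    annotations: list[GeneAnnotation],
    window_codons: int = START_WINDOW_CODONS,
) -> pd.DataFrame:
    """Per-gene start/body densities and the MUT/WT depletion score.

    Genes shorter than 2*window + 1 codons are skipped; ratios are NaN when
    the body density is zero.
    """
    rows = []
    for ann in annotations:
        n = ann.n_codons
        if n < 2 * window_codons + 1:
            continue
        row: dict = {"gene_id": ann.gene_id}
        ratios = {}
        for label, track in (("wt", coverage_wt), ("mut", coverage_mut)):
            per_codon = _per_codon_counts(track, ann)
            start = float(per_codon[:window_codons].mean())
            body = float(per_codon[window_codons : n - window_codons].mean())
            ratio = start / body if body > 0 else float("nan")
            row[f"start_density_{label}"] = start
            row[f"body_density_{label}"] = body
            row[f"start_ratio_{label}"] = ratio
            ratios[label] = ratio
        if ratios["wt"] and not np.isnan(ratios["wt"]) and ratios["wt"] > 0:
            row["depletion_score"] = ratios["mut"] / ratios["wt"]
        else:
            row["depletion_score"] = float("nan")
        rows.append(row)
    columns = ["gene_id"] + [
        f"{stat}_{label}"
        for label in ("wt", "mut")
        for stat in ("start_density", "body_density", "start_ratio")
    ] + ["depletion_score"]
    return pd.DataFrame(rows, columns=columns).set_index("gene_id")


def gene_codons(genome: GenomeSequence, ann: GeneAnnotation) -> list[str]:
    seq = genome.subseq(ann.start, ann.end)
    if ann.strand == "-":
        seq = revcomp(seq)
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def codon_pause_scores(
    track: CoverageTrack,
    annotations: list[GeneAnnotation],
    genome: GenomeSequence,
    exclude_edge_codons: int = EDGE_EXCLUDE_CODONS,
) -> pd.DataFrame:
    """Pooled per-codon occupancy scores for one condition.

    Per gene, the per-codon A-site density is divided by the gene's mean
    density (genes with zero signal are skipped); the normalized scores are
    pooled by codon identity across genes, excluding the first and last
    ``exclude_edge_codons`` codons. Uniform coverage gives every codon a
    score of 1.
    """
    pooled_sum: dict[str, float] = {}
    pooled_n: dict[str, int] = {}
    for ann in annotations:
        per_codon = _per_codon_counts(track, ann)
        mean = per_codon.mean()
        if mean == 0:
            continue
        scores = per_codon / mean
        codons = gene_codons(genome, ann)
        lo, hi = exclude_edge_codons, ann.n_codons - exclude_edge_codons
        if hi <= lo:
            continue
        for codon, score in zip(codons[lo:hi], scores[lo:hi]):
            pooled_sum[codon] = pooled_sum.get(codon, 0.0) + float(score)
            pooled_n[codon] = pooled_n.get(codon, 0) + 1
    rows = [
        {
            "codon": codon,
            "mean_score": pooled_sum[codon] / pooled_n[codon],
            "n_occurrences": pooled_n[codon],
        }
        for codon in sorted(pooled_sum)
    ]
    return pd.DataFrame(rows).set_index("codon")


def pause_ratio_table(
    scores_wt: pd.DataFrame, scores_mut: pd.DataFrame
) -> pd.DataFrame:
    """MUT/WT occupancy ratio per codon (outer-joined on codon identity)."""
    table = scores_wt.join(
        scores_mut, lsuffix="_wt", rsuffix="_mut", how="outer"
    )
    table["pause_ratio"] = table["mean_score_mut"] / table["mean_score_wt"]
    return table
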