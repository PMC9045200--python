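"""Per-gene counting, CPM normalization, and group summaries.

RPF signal is counted by A-site position: an A-site increments the gene
whose CDS (on the matching strand) contains it. RNA alignments are counted
by their integer midpoint, floor((start+end)/2), which avoids double
counting across adjacent genes of an operon. Signal outside any CDS goes to
an ``unassigned`` tally; positions covered by overlapping same-strand CDSs
are counted ``ambiguous`` and assigned to no gene.

Library sizes count only gene-assigned signal, so intergenic noise cannot
distort the CPM scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneAnnotation

VALID_CONDITIONS = {"WT", "MUT"}


@dataclass
class CountMatrix:
    """Genes x samples integer counts for one assay (RPF or RNA)."""

    assay: str
    counts: pd.DataFrame  # index: gene_id, columns: sample_id
    samples: pd.DataFrame  # index: sample_id; columns: condition, replicate

    def __post_init__(self) -> None:
        if self.assay not in ("RPF", "RNA"):
            raise ValueError("assay must be 'RPF' or 'RNA'")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns must match sample table order")
        bad = set(self.samples["condition"]) - VALID_CONDITIONS
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


class GeneLookup:
    """Position -> gene lookup arrays, one per (chromosome, strand)."""

    UNASSIGNED = -1
    AMBIGUOUS = -2

    def __init__(self, annotations: list[GeneAnnotation],
                 chrom_lengths: dict[str, int]):
        self.gene_ids = [a.gene_id for a in annotations]
        self._code = {g: i for i, g in enumerate(self.gene_ids)}
        self.arrays: dict[tuple[str, str], np.ndarray] = {
            (chrom, strand): np.full(length, self.UNASSIGNED, dtype=np.int32)
            for chrom, length in chrom_lengths.items()
            for strand in ("+", "-")
        }
        for ann in annotations:
            arr = self.arrays[(ann.chrom_id, ann.strand)]
            sl = slice(ann.start - 1, ann.end)
            occupied = arr[sl] != self.UNASSIGNED
            arr[sl] = np.where(occupied, self.AMBIGUOUS,
                               self._code[ann.gene_id])

    def codes_at(self, chrom: str, strand_plus: np.ndarray,
                 positions: np.ndarray) -> np.ndarray:
        plus = self.arrays[(chrom, "+")]
        minus = self.arrays[(chrom, "-")]
        idx = np.asarray(positions, dtype=np.int64) - 1
        return np.where(strand_plus, plus[idx], minus[idx])


@dataclass
class CountingResult:
    counts: pd.Series  # per gene
    unassigned: int
    ambiguous: int

    @property
    def assigned(self) -> int:
        return int(self.counts.sum())


def count_asites(
    lookup: GeneLookup,
    chrom: str,
    positions: np.ndarray,
    strand_plus: np.ndarray,
) -> CountingResult:
    """RPF counting: each A-site increments its containing same-strand CDS."""
    codes = lookup.codes_at(chrom, strand_plus, positions)
    return _tally(lookup, codes)


def count_rna_midpoints(
    lookup: GeneLookup,
    chrom: str,
    starts: np.ndarray,
    ends: np.ndarray,
    strand_plus: np.ndarray,
) -> CountingResult:
    """RNA counting by the alignment's integer midpoint."""
    midpoints = (np.asarray(starts) + np.asarray(ends)) // 2
    codes = lookup.codes_at(chrom, strand_plus, midpoints)
    return _tally(lookup, codes)


def _tally(lookup: GeneLookup, codes: np.ndarray) -> CountingResult:
    n_genes = len(lookup.gene_ids)
    assigned = codes[codes >= 0]
    per_gene = np.bincount(assigned, minlength=n_genes)
    return CountingResult(
        counts=pd.Series(per_gene, index=lookup.gene_ids, dtype=np.int64),
        unassigned=int((codes == lookup.UNASSIGNED).sum()),
        ambiguous=int((codes == lookup.AMBIGUOUS).sum()),
    )


def assemble_count_matrix(
    assay: str,
    columns: dict[str, pd.Series],
    samples: pd.DataFrame,
) -> CountMatrix:
    counts = pd.DataFrame(columns).loc[:, list(samples.index)]
    return CountMatrix(assay=assay, counts=counts, samples=samples)


def normalize_cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million assigned reads; columns sum to 1e6."""
    sizes = matrix.library_sizes
    zero = sizes[sizes == 0]
    if len(zero):
        raise ValueError(
            f"zero library size for sample(s): {list(zero.index)}"
        )
    return matrix.counts * 1.0e6 / sizes


@dataclass
class GroupSummary:
    mean_wt: pd.Series
    mean_mut: pd.Series
    sd_wt: pd.Series | None
    sd_mut: pd.Series | None
    replicates_wt: pd.DataFrame
    replicates_mut: pd.DataFrame


def group_means(values: pd.DataFrame, samples: pd.DataFrame) -> GroupSummary:
    """Arithmetic mean and sample SD (n-1) per condition per gene.

    With a single replicate in a condition the means are still returned and
    the SDs for that condition are None (flagged unavailable).
    """
    groups = {}
    for cond in ("WT", "MUT"):
        cols = samples.index[samples["condition"] == cond]
        if len(cols) == 0:
            raise ValueError(f"no samples for condition {cond}")
        sub = values[list(cols)]
        groups[cond] = sub
    sd = {
        cond: (sub.std(axis=1, ddof=1) if sub.shape[1] >= 2 else None)
        for cond, sub in groups.items()
    }
    return GroupSummary(
        mean_wt=groups["WT"].mean(axis=1),
        mean_mut=groups["MUT"].mean(axis=1),
        sd_wt=sd["WT"],
        sd_mut=sd["MUT"],
        replicates_wt=groups["WT"],
        replicates_mut=groups["MUT"],
    )


def low_expression_mask(
    cpm_rpf: pd.DataFrame,
    cpm_rna: pd.DataFrame,
    samples_rpf: pd.DataFrame,
    samples_rna: pd.DataFrame,
    min_cpm: float = 1.0,
) -> pd.Series:
    """Keep genes whose mean CPM reaches ``min_cpm`` in at least one of the
    four condition x assay cells; everything else is excluded from testing."""
    cells = []
    for cpm, samples in ((cpm_rpf, samples_rpf), (cpm_rna, samples_rna)):
        for cond in ("WT", "MUT"):
            cols = samples.index[samples["condition"] == cond]
            cells.append(cpm[list(cols)].mean(axis=1))
    keep = pd.concat(cells, axis=1).max(axis=1) >= min_cpm
    keep.name = "keep"
    return keep
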