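"""Length filtering, exact-match alignment, and A-site assignment.

Footprints are kept when their length lies in [20, 40] nt inclusive. Reads
are aligned by exact string match against both strands of the genome; only
reads matching exactly one locus are used (multi-mappers are discarded and
counted, reads containing N never align).

The ribosomal A-site is assigned at a fixed offset from the 3' end of the
aligned footprint: counting the 3'-terminal aligned base as position 1, the
A-site nucleotide is position ``offset`` (default 12). On the plus strand
that is ``end - offset + 1``; on the minus strand ``start + offset - 1``.
RNA-seq alignments are never offset; they are counted by their midpoint
downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import CoverageTrack, GenomeSequence, ReadRecord, revcomp


class AlignVerdict(enum.Enum):
    UNALIGNED = "unaligned"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Alignment:
    read_id: str
    chrom_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    length: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.length:
            raise ValueError("alignment span does not match read length")


@dataclass(frozen=True)
class AsiteAssignment:
    read_id: str
    chrom_id: str
    position: int  # 1-based nt of the A-site
    strand: str


def filter_by_length(
    reads: Iterable[ReadRecord], min_len: int = 20, max_len: int = 40
) -> tuple[list[ReadRecord], int]:
    """Keep reads with min_len <= length <= max_len (both ends inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept, dropped = [], 0
    for read in reads:
        if min_len <= len(read) <= max_len:
            kept.append(read)
        else:
            dropped += 1
    return kept, dropped


class GenomeIndex:
    """Exact-match index over both strands of one or more chromosomes.

    A k-mer prefix table over the forward strands locates candidates; a
    full-string comparison confirms them. Reverse-strand hits are found by
    searching the reverse complement of the query on the forward strand.
    """

    def __init__(self, genomes: Sequence[GenomeSequence], k: int = 20):
        self.k = k
        self.genomes = {g.chrom_id: g.sequence for g in genomes}
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genomes.items():
            for i in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[i : i + k], []).append((chrom, i))

    def _forward_matches(self, query: str) -> list[tuple[str, int]]:
        """All (chrom, 0-based start) exact forward-strand matches."""
        n = len(query)
        if n >= self.k:
            hits = []
            for chrom, i in self._kmers.get(query[: self.k], ()):
                if self.genomes[chrom][i : i + n] == query:
                    hits.append((chrom, i))
            return hits
        hits = []
        for chrom, seq in self.genomes.items():
            i = seq.find(query)
            while i != -1:
                hits.append((chrom, i))
                i = seq.find(query, i + 1)
        return hits

    def locate(self, sequence: str) -> list[tuple[str, int, str]]:
        """All (chrom, 0-based start, strand) matches across both strands."""
        fwd = [(c, i, "+") for c, i in self._forward_matches(sequence)]
        rev = [
            (c, i, "-") for c, i in self._forward_matches(revcomp(sequence))
        ]
        return fwd + rev


def align_exact(
    read: ReadRecord, index: GenomeIndex
) -> Alignment | AlignVerdict:
    """Align one read; unique locus required, N-containing reads never map."""
    if "N" in read.sequence:
        return AlignVerdict.UNALIGNED
    hits = index.locate(read.sequence)
    if not hits:
        return AlignVerdict.UNALIGNED
    if len(hits) > 1:
        return AlignVerdict.AMBIGUOUS
    chrom, i, strand = hits[0]
    return Alignment(
        read_id=read.read_id,
        chrom_id=chrom,
        start=i + 1,
        end=i + len(read.sequence),
        strand=strand,
        length=len(read.sequence),
    )


def align_sequences_bulk(
    ids_and_seqs: Iterable[tuple[str, str]],
    index: GenomeIndex,
    min_len: int = 20,
    max_len: int = 40,
) -> dict:
    """Filter + align a stream of (read_id, sequence); arrays out.

    Returns dict with numpy arrays ``start``, ``end`` (1-based inclusive),
    ``strand`` (bool, True for '+'), list ``chrom``, and the counters
    ``n_input``, ``n_length_dropped``, ``n_unaligned``, ``n_ambiguous``.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    starts: list[int] = []
    ends: list[int] = []
    plus: list[bool] = []
    chroms: list[str] = []
    n_input = n_len = n_un = n_amb = 0
    fwd = index._forward_matches
    for _rid, seq in ids_and_seqs:
        n_input += 1
        n = len(seq)
        if n < min_len or n > max_len:
            n_len += 1
            continue
        if "N" in seq:
            n_un += 1
            continue
        hits_f = fwd(seq)
        hits_r = fwd(revcomp(seq))
        total = len(hits_f) + len(hits_r)
        if total == 0:
            n_un += 1
            continue
        if total > 1:
            n_amb += 1
            continue
        if hits_f:
            chrom, i = hits_f[0]
            plus.append(True)
        else:
            chrom, i = hits_r[0]
            plus.append(False)
        starts.append(i + 1)
        ends.append(i + n)
        chroms.append(chrom)
    return {
        "start": np.array(starts, dtype=np.int64),
        "end": np.array(ends, dtype=np.int64),
        "strand_plus": np.array(plus, dtype=bool),
        "chrom": chroms,
        "n_input": n_input,
        "n_length_dropped": n_len,
        "n_unaligned": n_un,
        "n_ambiguous": n_amb,
    }


def assign_asite(
    alignment: Alignment, offset: int = 12
) -> AsiteAssignment | None:
    """A-site nucleotide at ``offset`` from the 3' end (3'-terminal = 1).

    Returns None (unassignable) when the footprint is shorter than the
    offset.
    """
    if alignment.length < offset:
        return None
    if alignment.strand == "+":
        pos = alignment.end - offset + 1
    else:
        pos = alignment.start + offset - 1
    return AsiteAssignment(
        alignment.read_id, alignment.chrom_id, pos, alignment.strand
    )


def asite_positions(
    starts: np.ndarray,
    ends: np.ndarray,
    strand_plus: np.ndarray,
    offset: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized A-site positions; returns (positions, assignable_mask)."""
    lengths = ends - starts + 1
    ok = lengths >= offset
    pos = np.where(strand_plus, ends - offset + 1, starts + offset - 1)
    return pos[ok], ok


def build_coverage(
    assignments: Iterable[AsiteAssignment],
    genomes: Sequence[GenomeSequence],
) -> CoverageTrack:
    """Per-base A-site counts; total signal equals the assignment count."""
    track = CoverageTrack({g.chrom_id: len(g) for g in genomes})
    buckets: dict[tuple[str, str], list[int]] = {}
    for a in assignments:
        if a.chrom_id not in track.chrom_lengths:
            raise ValueError(f"unknown chromosome {a.chrom_id!r}")
        buckets.setdefault((a.chrom_id, a.strand), []).append(a.position)
    for (chrom, strand), positions in buckets.items():
        track.add_positions(chrom, strand, np.array(positions))
    return track


def coverage_from_arrays(
    chrom_id: str,
    positions: np.ndarray,
    strand_plus: np.ndarray,
    genomes: Sequence[GenomeSequence],
) -> CoverageTrack:
    track = CoverageTrack({g.chrom_id: len(g) for g in genomes})
    track.add_positions(chrom_id, "+", positions[strand_plus])
    track.add_positions(chrom_id, "-", positions[~strand_plus])
    return track
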