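"""Readers and writers for the plain-text formats the pipeline touches.

Coordinate convention: every in-memory coordinate is 1-based inclusive (the
GFF convention). The single place this is converted is :func:`write_bedgraph`,
which emits 0-based half-open intervals as the bedGraph format requires.
Keeping one conversion point avoids off-by-one drift between modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
READ_ALPHABET = frozenset("ACGTN")
STOP_CODONS = ("TAA", "TAG", "TGA")

_RC = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """An input file violates the expected plain-text format."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A chromosome: uppercase DNA over {A,C,G,T}."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.chrom_id!r}")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.chrom_id!r} contains non-ACGT characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Substring at 1-based inclusive [start, end]."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise ValueError(f"[{start},{end}] outside 1..{len(self.sequence)}")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class GeneAnnotation:
    """A CDS feature with operon membership.

    ``start``/``end`` are 1-based inclusive genomic coordinates; the CDS
    length must be a whole number of codons.
    """

    gene_id: str
    operon_id: str
    chrom_id: str
    start: int
    end: int
    strand: str
    feature: str = "CDS"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(
                f"{self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")
        if len(self) % 3 != 0:
            raise FormatError(
                f"{self.gene_id}: CDS length {len(self)} not divisible by 3"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def n_codons(self) -> int:
        return len(self) // 3


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, sequence over {A,C,G,T,N}, Sanger quality."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FormatError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )
        bad = set(self.sequence) - READ_ALPHABET
        if bad:
            raise FormatError(
                f"read {self.read_id!r} contains characters outside ACGTN: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    path = Path(path)
    with path.open() as handle:
        # SimpleFastaParser silently skips leading junk; enforce the header
        # rule explicitly so a malformed file fails loudly with its line.
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path.name}:{lineno}: expected FASTA header "
                        f"starting with '>'"
                    )
                break
        handle.seek(0)
        records = [
            GenomeSequence(title.split()[0], seq.upper())
            for title, seq in SimpleFastaParser(handle)
        ]
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path,
                width: int = 70) -> None:
    with Path(path).open("w") as out:
        for rec in records:
            out.write(f">{rec.chrom_id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path) -> list[ReadRecord]:
    path = Path(path)
    records: list[ReadRecord] = []
    with path.open() as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:  # truncated / mismatched record
                raise FormatError(
                    f"{path.name}: malformed FASTQ record "
                    f"{len(records) + 1}: {exc}"
                ) from exc
            records.append(ReadRecord(title.split()[0], seq.upper(), qual))
    return records


def iter_fastq_sequences(path: str | Path) -> Iterable[tuple[str, str]]:
    """Fast (id, sequence) iterator for bulk pipeline use."""
    with Path(path).open() as handle:
        for title, seq, _qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq.upper()


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with Path(path).open("w") as out:
        for rec in records:
            out.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")


# ---------------------------------------------------------------------------
# GFF3 (CDS-only subset)


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Parse the CDS-only GFF3 subset.

    Only ``CDS`` features are consumed; anything else is skipped (count
    logged). Attributes must carry ``ID=``; ``Parent=`` gives the operon and
    defaults to the gene id itself.
    """
    path = Path(path)
    annotations: list[GeneAnnotation] = []
    seen: set[str] = set()
    skipped = 0
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 9 tab-separated GFF "
                    f"fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, \
                attrs = fields
            if feature != "CDS":
                skipped += 1
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise FormatError(
                    f"{path.name}:{lineno}: end {end} < start {start}"
                )
            attr_map = _parse_attributes(attrs, path.name, lineno)
            gene_id = attr_map.get("ID")
            if gene_id is None:
                raise FormatError(f"{path.name}:{lineno}: missing ID= attribute")
            if gene_id in seen:
                raise FormatError(
                    f"{path.name}:{lineno}: duplicate gene ID {gene_id!r}"
                )
            seen.add(gene_id)
            annotations.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    operon_id=attr_map.get("Parent", gene_id),
                    chrom_id=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    if skipped:
        log.info("read_annotation: skipped %d non-CDS feature(s)", skipped)
    return annotations


def _parse_attributes(attrs: str, fname: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise FormatError(f"{fname}:{lineno}: bad attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        out[key] = value
    return out


def write_annotation(annotations: Iterable[GeneAnnotation],
                     path: str | Path) -> None:
    with Path(path).open("w") as out:
        out.write("##gff-version 3\n")
        for ann in annotations:
            attrs = f"ID={ann.gene_id}"
            if ann.operon_id != ann.gene_id:
                attrs += f";Parent={ann.operon_id}"
            out.write(
                f"{ann.chrom_id}\tribotide\tCDS\t{ann.start}\t{ann.end}\t.\t"
                f"{ann.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Coverage tracks and bedGraph


class CoverageTrack:
    """Per-(chromosome, strand) dense base-resolution signal.

    Vectors are indexed so that array index 0 holds 1-based genome position 1.
    """

    def __init__(self, chrom_lengths: dict[str, int]) -> None:
        self.chrom_lengths = dict(chrom_lengths)
        self.data: dict[tuple[str, str], np.ndarray] = {
            (chrom, strand): np.zeros(length, dtype=float)
            for chrom, length in self.chrom_lengths.items()
            for strand in ("+", "-")
        }

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[(chrom, strand)]

    def add_positions(self, chrom: str, strand: str,
                      positions: np.ndarray) -> None:
        """Increment the track at 1-based positions (one count each)."""
        positions = np.asarray(positions, dtype=np.int64)
        length = self.chrom_lengths[chrom]
        if positions.size and (positions.min() < 1 or positions.max() > length):
            raise ValueError(
                f"position outside 1..{length} on {chrom}{strand} "
                f"(upstream bug)"
            )
        self.data[(chrom, strand)] += np.bincount(
            positions - 1, minlength=length
        ).astype(float)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        out = CoverageTrack(self.chrom_lengths)
        for key, vec in self.data.items():
            out.data[key] = vec * factor
        return out


def _format_value(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def write_bedgraph(track: CoverageTrack, path: str | Path, strand: str,
                   name: str | None = None) -> None:
    """Write one strand of a track as bedGraph (0-based half-open).

    Runs of equal nonzero value are merged into single intervals; zero runs
    are omitted entirely.
    """
    path = Path(path)
    name = name or f"{path.stem}"
    with path.open("w") as out:
        out.write(f'track type=bedGraph name="{name}"\n')
        for chrom in track.chrom_lengths:
            vec = track.get(chrom, strand)
            if vec.size == 0:
                continue
            # run-length segmentation
            change = np.flatnonzero(np.diff(vec) != 0)
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [vec.size]))
            for s, e in zip(starts, ends):
                value = vec[s]
                if value == 0:
                    continue
                out.write(f"{chrom}\t{s}\t{e}\t{_format_value(value)}\n")


def read_bedgraph_into(track: CoverageTrack, path: str | Path,
                       strand: str) -> CoverageTrack:
    """Load one strand's bedGraph data lines back into a track."""
    with Path(path).open() as handle:
        for line in handle:
            if line.startswith("track") or not line.strip():
                continue
            chrom, start, end, value = line.rstrip("\n").split("\t")
            track.get(chrom, strand)[int(start) : int(end)] += float(value)
    return track


def read_bedgraph_total(path: str | Path) -> float:
    """Sum of interval-length x value over a bedGraph file (for checks)."""
    total = 0.0
    with Path(path).open() as handle:
        for line in handle:
            if line.startswith("track") or not line.strip():
                continue
            chrom, start, end, value = line.split("\t")
            total += (int(end) - int(start)) * float(value)
    return total
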