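"""Sequence-logo statistics for protein loop alignments.

Implements the Schneider-Stephens quantities that underlie a Weblogo-style
display for a 20-letter amino-acid alphabet: per-column frequencies over
non-gap residues, information content

    R = log2(20) - H - e_n,   H = -sum f log2 f,

with the optional Basharin small-sample correction e_n = 19 / (2 ln2 n),
letter heights f * R, plus the basic/acidic charge-class fractions and a
conserved/variable call used to characterize exit-tunnel loop positions.

Gaps (and non-standard residues X, B, Z) reduce the effective count n
rather than acting as a 21st symbol, matching Weblogo defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from Bio.SeqIO.FastaIO import SimpleFastaParser

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASIC = "KRH"
ACIDIC = "DE"
MAX_BITS = float(np.log2(20))
_GAPLIKE = set("-.XBZ*")


@dataclass(frozen=True)
class AlignmentColumnProfile:
    position: int  # 1-based column index
    counts: dict[str, int]
    gap_count: int

    @property
    def n_eff(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.n_eff
        if n == 0:
            return {}
        return {aa: c / n for aa, c in self.counts.items() if c > 0}


def read_alignment_fasta(path: str | Path) -> list[tuple[str, str]]:
    with Path(path).open() as handle:
        return [(t.split()[0], s.upper()) for t, s in SimpleFastaParser(handle)]


def column_profiles(
    sequences: list[tuple[str, str]] | list[str],
) -> list[AlignmentColumnProfile]:
    """One profile per alignment column; all sequences must share a length."""
    seqs = [s if isinstance(s, str) else s[1] for s in sequences]
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    profiles = []
    for col in range(length):
        counts = {aa: 0 for aa in AMINO_ACIDS}
        gaps = 0
        for seq in seqs:
            ch = seq[col].upper()
            if ch in _GAPLIKE:
                gaps += 1
            elif ch in counts:
                counts[ch] += 1
            else:
                raise ValueError(f"unknown residue {ch!r} in column {col + 1}")
        profiles.append(
            AlignmentColumnProfile(position=col + 1, counts=counts,
                                   gap_count=gaps)
        )
    return profiles


def information_content(
    profile: AlignmentColumnProfile, small_sample_correction: bool = False
) -> float:
    """R = log2(20) - H - e, clamped at 0; NaN for an all-gap column."""
    n = profile.n_eff
    if n == 0:
        return float("nan")
    freqs = np.array(list(profile.frequencies.values()))
    entropy = float(-(freqs * np.log2(freqs)).sum())
    correction = 19.0 / (2.0 * np.log(2.0) * n) if small_sample_correction \
        else 0.0
    return max(0.0, MAX_BITS - entropy - correction)


def letter_heights(
    profile: AlignmentColumnProfile, small_sample_correction: bool = False
) -> dict[str, float]:
    """Per-residue logo heights f * R; they sum to the column's info bits."""
    r = information_content(profile, small_sample_correction)
    return {aa: f * r for aa, f in profile.frequencies.items()}


def charge_enrichment(profile: AlignmentColumnProfile
                      ) -> tuple[float, float]:
    """(basic K/R/H fraction, acidic D/E fraction) among non-gap residues."""
    freqs = profile.frequencies
    basic = sum(freqs.get(aa, 0.0) for aa in BASIC)
    acidic = sum(freqs.get(aa, 0.0) for aa in ACIDIC)
    return basic, acidic


def classify_variability(
    profile: AlignmentColumnProfile, dominant_cutoff: float = 0.5
) -> str:
    """'conserved' iff the most frequent residue reaches the cutoff."""
    freqs = profile.frequencies
    if not freqs:
        return "variable"
    return "conserved" if max(freqs.values()) >= dominant_cutoff \
        else "variable"


def logo_table(
    sequences: list[tuple[str, str]] | list[str],
    small_sample_correction: bool = False,
    dominant_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Position-wise logo statistics table (heights, bits, charge, class)."""
    rows = []
    for profile in column_profiles(sequences):
        basic, acidic = charge_enrichment(profile)
        row = {
            "position": profile.position,
            "n_eff": profile.n_eff,
            "gap_count": profile.gap_count,
            "info_bits": information_content(profile,
                                             small_sample_correction),
            "basic_fraction": basic,
            "acidic_fraction": acidic,
            "class": classify_variability(profile, dominant_cutoff),
        }
        heights = letter_heights(profile, small_sample_correction)
        for aa in AMINO_ACIDS:
            row[f"height_{aa}"] = heights.get(aa, 0.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("position")
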