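"""Length filter, exact-match alignment, A-site convention, coverage."""

import numpy as np
import pytest

from ribotide.io import GenomeSequence, ReadRecord, revcomp
from ribotide.mapping import (
    Alignment,
    AlignVerdict,
    GenomeIndex,
    align_exact,
    align_sequences_bulk,
    asite_positions,
    assign_asite,
    build_coverage,
    filter_by_length,
)


def _read(seq, rid="r"):
    return ReadRecord(rid, seq, "~" * len(seq))


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(123)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    return GenomeSequence("chr1", seq)


@pytest.fixture(scope="module")
def index(toy_genome):
    return GenomeIndex([toy_genome])


class TestFilterByLength:
    def test_inclusive_bounds(self):
        reads = [_read("A" * n, f"r{n}") for n in (19, 20, 40, 41)]
        kept, dropped = filter_by_length(reads)
        assert [len(r) for r in kept] == [20, 40]
        assert dropped == 2

    def test_empty_input(self):
        assert filter_by_length([]) == ([], 0)

    def test_exact_boundary(self):
        kept, dropped = filter_by_length([_read("A" * 28)], 28, 28)
        assert len(kept) == 1 and dropped == 0

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            filter_by_length([], 30, 20)


class TestAlignExact:
    def test_unique_forward_locus(self, toy_genome, index):
        read = _read(toy_genome.subseq(101, 130))
        result = align_exact(read, index)
        assert isinstance(result, Alignment)
        assert (result.start, result.end, result.strand) == (101, 130, "+")

    def test_unique_reverse_locus(self, toy_genome, index):
        read = _read(revcomp(toy_genome.subseq(101, 130)))
        result = align_exact(read, index)
        assert (result.start, result.end, result.strand) == (101, 130, "-")

    def test_two_loci_ambiguous(self):
        genome = GenomeSequence("chr1",
                                "ACGTACGTACGTACGTACGTACGT" * 2 + "GGGG")
        idx = GenomeIndex([genome])
        read = _read(genome.sequence[:24])
        assert align_exact(read, idx) is AlignVerdict.AMBIGUOUS

    def test_n_read_unaligned(self, toy_genome, index):
        seq = toy_genome.subseq(101, 130)
        read = _read("N" + seq[1:])
        assert align_exact(read, index) is AlignVerdict.UNALIGNED

    def test_absent_sequence_unaligned(self, index):
        assert align_exact(_read("A" * 25), index) is AlignVerdict.UNALIGNED

    def test_alignment_substring_verification(self, toy_genome, index):
        rng = np.random.default_rng(9)
        for _ in range(50):
            start = int(rng.integers(1, len(toy_genome) - 40))
            length = int(rng.integers(20, 41))
            frag = toy_genome.subseq(start, start + length - 1)
            if rng.random() < 0.5:
                frag = revcomp(frag)
            result = align_exact(_read(frag), index)
            if isinstance(result, Alignment):
                back = toy_genome.subseq(result.start, result.end)
                if result.strand == "-":
                    back = revcomp(back)
                assert back == frag


class TestAsiteAssignment:
    def test_plus_strand_offset(self):
        a = Alignment("r", "chr1", 101, 130, "+", 30)
        assert assign_asite(a, 12).position == 119

    def test_minus_strand_offset(self):
        a = Alignment("r", "chr1", 101, 130, "-", 30)
        assert assign_asite(a, 12).position == 112

    def test_offset_one_is_three_prime_base(self):
        a = Alignment("r", "chr1", 101, 130, "+", 30)
        assert assign_asite(a, 1).position == 130

    def test_short_footprint_unassignable(self):
        a = Alignment("r", "chr1", 101, 110, "+", 10)
        assert assign_asite(a, 12) is None

    def test_vectorized_matches_scalar(self):
        starts = np.array([101, 101, 101])
        ends = np.array([130, 130, 110])
        plus = np.array([True, False, True])
        pos, ok = asite_positions(starts, ends, plus, offset=12)
        assert pos.tolist() == [119, 112]
        assert ok.tolist() == [True, True, False]

    def test_convention_recovers_codon_middle(self, toy_genome, index):
        """A footprint anchored 11 nt downstream of a codon's middle base
        maps back to exactly that base under the 12-offset rule."""
        middle = 205
        end3 = middle + 11
        frag = toy_genome.subseq(end3 - 27, end3)  # 28-mer, 3' end at end3
        result = align_exact(_read(frag), index)
        if isinstance(result, Alignment):  # skip silently if multi-mapping
            assert assign_asite(result, 12).position == middle
        # minus strand mirror: 3' terminal base at genomic position `middle-11`
        start3 = middle - 11
        frag = revcomp(toy_genome.subseq(start3, start3 + 27))
        result = align_exact(_read(frag), index)
        if isinstance(result, Alignment):
            assert result.strand == "-"
            assert assign_asite(result, 12).position == middle


class TestCoverage:
    def test_counts_accumulate(self, toy_genome):
        assignments = [
            assign_asite(Alignment("r", "chr1", 101, 130, "+", 30))
            for _ in range(3)
        ]
        track = build_coverage(assignments, [toy_genome])
        vec = track.get("chr1", "+")
        assert vec[118] == 3 and vec.sum() == 3

    def test_empty_input_zero_track(self, toy_genome):
        track = build_coverage([], [toy_genome])
        assert track.total() == 0

    def test_total_equals_input_count(self, toy_genome):
        rng = np.random.default_rng(2)
        assignments = [
            assign_asite(
                Alignment("r", "chr1", int(s), int(s) + 29, "+", 30)
            )
            for s in rng.integers(1, 500, size=200)
        ]
        track = build_coverage(assignments, [toy_genome])
        assert track.total() == 200


class TestBulkAlignment:
    def test_counters_conserve_input(self, toy_genome, index):
        seqs = [
            ("r1", toy_genome.subseq(50, 77)),          # unique
            ("r2", "A" * 19),                            # too short
            ("r3", "N" * 28),                            # N rule
            ("r4", "G" * 41),                            # too long
        ]
        res = align_sequences_bulk(seqs, index)
        assert res["n_input"] == 4
        total = (len(res["start"]) + res["n_length_dropped"]
                 + res["n_unaligned"] + res["n_ambiguous"])
        assert total == 4
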