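"""Aligner correctness against the exhaustive Hamming oracle, miRNA soft-tail
semantics and multi-mapping fractionation."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import alignment_tuples, brute_force_alignments, random_seq
from nmsrna.mapper import (
    Alignment,
    AlignmentError,
    align_mirna,
    align_read,
    fractionate,
)
from nmsrna.preprocess import Read
from nmsrna.references import ReferenceRecord, build_reference_index


@pytest.fixture(scope="module")
def toy_index(toy_records):
    return build_reference_index(toy_records, seed_length=7)


class TestAlignRead:
    def test_exact_unique_hit(self, toy_records, toy_index):
        rec = toy_records[0]
        read = Read("q", rec.sequence[10:30])
        alns = align_read(read, toy_index, max_mismatch=0)
        exact = [a for a in alns if a.ref_id == rec.id and a.ref_start == 11]
        assert exact and exact[0].ref_end == 30 and exact[0].mismatches == ()

    def test_planted_substitution_coordinates(self, toy_records, toy_index):
        rec = toy_records[1]
        seq = list(rec.sequence[5:30])
        orig = seq[9]
        seq[9] = "A" if orig != "A" else "C"
        alns = align_read(Read("q", "".join(seq)), toy_index, max_mismatch=1)
        hit = next(a for a in alns if a.ref_id == rec.id and a.ref_start == 6)
        (mm,) = hit.mismatches
        assert mm.ref_position == 15  # 1-based: start 6 + offset 9
        assert mm.ref_base == orig

    def test_too_short_read_rejected(self, toy_index):
        with pytest.raises(AlignmentError, match="length"):
            align_read(Read("q", "ACGTACGTACGTA"), toy_index)

    def test_no_indels_and_span_invariant(self, toy_records, toy_index):
        rng = np.random.default_rng(11)
        for _ in range(100):
            rec = toy_records[int(rng.integers(0, len(toy_records)))]
            n = int(rng.integers(15, 40))
            if rec.length < n:
                continue
            s = int(rng.integers(0, rec.length - n + 1))
            read = Read("q", rec.sequence[s : s + n])
            for a in align_read(read, toy_index):
                assert a.ref_end - a.ref_start + 1 + a.soft_tail_3p == n

    @pytest.mark.parametrize("max_mismatch", [0, 1])
    def test_oracle_equivalence_500_reads(self, toy_records, toy_index, max_mismatch):
        """Seed-and-verify returns exactly the exhaustive Hamming scan's
        placements, mismatch coordinates included, for 0 and 1 allowed
        substitutions."""
        rng = np.random.default_rng(500 + max_mismatch)
        for i in range(500):
            if i % 3 == 0:  # fully random read (usually unmappable)
                seq = random_seq(rng, int(rng.integers(15, 41)))
            else:  # fragment of a reference with 0-2 planted substitutions
                rec = toy_records[int(rng.integers(0, len(toy_records)))]
                n = int(rng.integers(15, min(41, rec.length + 1)))
                s = int(rng.integers(0, rec.length - n + 1))
                chars = list(rec.sequence[s : s + n])
                for _ in range(int(rng.integers(0, 3))):
                    j = int(rng.integers(0, n))
                    chars[j] = "ACGT"[int(rng.integers(0, 4))]
                seq = "".join(chars)
            got = alignment_tuples(align_read(Read("q", seq), toy_index, max_mismatch))
            assert got == brute_force_alignments(seq, toy_records, max_mismatch)


@pytest.fixture(scope="module")
def mirna_index():
    rng = np.random.default_rng(21)
    recs = [
        ReferenceRecord(
            id=f"mir{i}", rna_class="miRNA", subclass="", sequence=random_seq(rng, 22)
        )
        for i in range(10)
    ]
    return build_reference_index(recs, seed_length=7)


class TestAlignMirna:
    def test_exact_mature_mirna_no_tail(self, mirna_index):
        rec = mirna_index.records[0]
        (aln,) = align_mirna(Read("q", rec.sequence), mirna_index)
        assert (aln.soft_tail_3p, aln.mismatches, aln.ref_start, aln.ref_end) == (0, (), 1, 22)

    def test_two_nontemplated_additions(self, mirna_index):
        rec = mirna_index.records[1]
        (aln,) = align_mirna(Read("q", rec.sequence + "TT"), mirna_index)
        # reference ends at 22, so the two extra bases can only be soft tail
        assert aln.soft_tail_3p == 2 and aln.mismatches == ()

    def test_internal_mismatch_plus_one_addition(self, mirna_index):
        rec = mirna_index.records[2]
        chars = list(rec.sequence)
        chars[10] = "A" if chars[10] != "A" else "C"
        read = Read("q", "".join(chars) + "G")
        alns = [a for a in align_mirna(read, mirna_index) if a.ref_id == rec.id]
        (aln,) = alns
        assert aln.soft_tail_3p == 1 and len(aln.mismatches) == 1
        assert aln.mismatches[0].ref_position == 11

    def test_exhaustive_tail_placement_oracle(self, mirna_index):
        """Every (tail, placement) interpretation enumerated by brute force
        agrees with align_mirna's chosen minimal-mismatch interpretation."""
        rng = np.random.default_rng(77)
        records = mirna_index.records
        for _ in range(200):
            rec = records[int(rng.integers(0, len(records)))]
            chars = list(rec.sequence)
            for _ in range(int(rng.integers(0, 2))):
                j = int(rng.integers(0, 22))
                chars[j] = "ACGT"[int(rng.integers(0, 4))]
            tail = "".join("ACGT"[int(rng.integers(0, 4))] for _ in range(int(rng.integers(0, 3))))
            seq = "".join(chars) + tail
            # oracle: best (mismatch count, tail) per placement over t = 0..2
            best: dict[tuple[str, int], tuple[int, int]] = {}
            for t in range(3):
                core = seq[: len(seq) - t]
                for rid, start, mm in brute_force_alignments(core, records, 1):
                    key = (rid, start)
                    cand = (len(mm), t)
                    if key not in best or cand < best[key]:
                        best[key] = cand
            got = {
                (a.ref_id, a.ref_start): (len(a.mismatches), a.soft_tail_3p)
                for a in align_mirna(Read("q", seq), mirna_index)
            }
            assert got == best

    def test_terminal_substitution_reads_as_nontemplated_addition(self, mirna_index):
        """A 3'-terminal substitution is ambiguous: a 1-mismatch full placement
        or a 0-mismatch placement with a 1-base tail.  The fewer-internal-
        mismatch (non-templated addition) interpretation wins."""
        rec = mirna_index.records[3]
        chars = list(rec.sequence)
        chars[21] = "A" if chars[21] != "A" else "C"
        (aln,) = [a for a in align_mirna(Read("q", "".join(chars)), mirna_index) if a.ref_id == rec.id]
        assert aln.soft_tail_3p == 1 and aln.mismatches == ()


class TestFractionate:
    def _aln(self, rid):
        return Alignment(read_id="r", ref_id=rid, ref_start=1, ref_end=20)

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_even_split(self, k):
        alns = fractionate([self._aln(f"x{i}") for i in range(k)])
        assert all(abs(a.weight - 1.0 / k) < 1e-12 for a in alns)
        assert abs(sum(a.weight for a in alns) - 1.0) < 1e-12

    def test_empty_rejected(self):
        with pytest.raises(AlignmentError):
            fractionate([])

    def test_mixed_reads_rejected(self):
        a = Alignment(read_id="r1", ref_id="x", ref_start=1, ref_end=20)
        b = Alignment(read_id="r2", ref_id="y", ref_start=1, ref_end=20)
        with pytest.raises(AlignmentError):
            fractionate([a, b])
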