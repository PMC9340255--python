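"""Exact ungapped alignment with at most one substitution and no indels.

The aligner is seed-and-verify with pigeonhole halves: a read is split into
two non-overlapping seeds of the index seed length; a placement with <= 1
substitution leaves at least one seed exact, so exact-seed lookup followed by
full Hamming verification enumerates ALL valid placements — the same answer a
brute-force scan over every offset of every reference would give, at a
fraction of the cost.

miRNA alignment additionally tolerates up to two non-templated 3' additions:
bases appended post-transcriptionally to miRNA 3' ends that do not match the
reference.  A read is tried with 0, 1, 2 trailing bases set aside; for a given
placement the interpretation with the fewest internal mismatches wins, and on
ties the smaller soft tail (templated interpretation) is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import Read
from .references import ReferenceIndex


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class Mismatch:
    """One substitution, keyed by the REFERENCE base (1-based coordinate)."""

    ref_position: int
    ref_base: str
    read_base: str

    def __post_init__(self) -> None:
        if self.ref_base == self.read_base:
            raise AlignmentError("mismatch with identical bases")


@dataclass(frozen=True)
class Alignment:
    """A read placed ungapped on one reference, forward strand, 1-based inclusive."""

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    mismatches: tuple[Mismatch, ...] = ()
    soft_tail_3p: int = 0
    weight: float = 1.0

    @property
    def aligned_length(self) -> int:
        return self.ref_end - self.ref_start + 1


def _placements(
    seq: bytes, index: ReferenceIndex, max_mismatch: int
) -> list[tuple[int, int, np.ndarray]]:
    """All (record_index, start0, mismatch_offsets) of seq with <= max_mismatch subs."""
    k = index.seed_length
    arr = np.frombuffer(seq, dtype=np.uint8)
    n = len(seq)
    candidates: set[tuple[int, int]] = set()
    if n >= 2 * k:
        for s in (0, k):
            for ri, off in index.seed_table.get(seq[s : s + k], ()):
                start = off - s
                if 0 <= start and start + n <= len(index.encoded[ri]):
                    candidates.add((ri, start))
    else:
        # Too short for two seeds: exact full scan (used only for the short
        # miRNA cores that arise after setting aside non-templated tail bases).
        for ri, ref in enumerate(index.encoded):
            if len(ref) < n:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref, n)
            hits = np.nonzero((windows != arr).sum(axis=1) <= max_mismatch)[0]
            candidates.update((ri, int(s)) for s in hits)
    out = []
    for ri, start in candidates:
        diff = np.nonzero(index.encoded[ri][start : start + n] != arr)[0]
        if len(diff) <= max_mismatch:
            out.append((ri, start, diff))
    return out


def _to_alignment(
    read: Read,
    index: ReferenceIndex,
    ri: int,
    start0: int,
    diff: np.ndarray,
    core_len: int,
    soft_tail: int,
) -> Alignment:
    rec = index.records[ri]
    mms = tuple(
        Mismatch(
            ref_position=start0 + int(d) + 1,
            ref_base=rec.sequence[start0 + int(d)],
            read_base=read.sequence[int(d)],
        )
        for d in diff
    )
    return Alignment(
        read_id=read.id,
        ref_id=rec.id,
        ref_start=start0 + 1,
        ref_end=start0 + core_len,
        mismatches=mms,
        soft_tail_3p=soft_tail,
    )


def align_read(read: Read, index: ReferenceIndex, max_mismatch: int = 1) -> list[Alignment]:
    """All ungapped full-length placements of the read with <= max_mismatch substitutions.

    Output is deterministic, sorted by (ref_id, ref_start).  Reads shorter
    than twice the index seed length are rejected (the pigeonhole guarantee
    needs two non-overlapping seeds).
    """
    n = read.length
    if n < 2 * index.seed_length:
        raise AlignmentError(
            f"read {read.id!r} length {n} < 2 x seed length {index.seed_length}"
        )
    seq = read.sequence.encode("ascii")
    alns = [
        _to_alignment(read, index, ri, start, diff, n, 0)
        for ri, start, diff in _placements(seq, index, max_mismatch)
    ]
    alns.sort(key=lambda a: (a.ref_id, a.ref_start))
    return alns


def align_mirna(
    read: Read,
    mirna_index: ReferenceIndex,
    max_internal_mismatch: int = 1,
    max_nt_addition: int = 2,
) -> list[Alignment]:
    """miRNA-mode alignment: up to ``max_nt_addition`` non-templated 3' bases.

    For each soft-tail size t the read core (read minus t trailing bases) is
    placed ungapped with <= max_internal_mismatch substitutions.  Placements
    sharing (ref_id, ref_start) keep the interpretation with the fewest
    internal mismatches, ties resolved toward the smaller tail.
    """
    n = read.length
    if n < 2 * mirna_index.seed_length:
        raise AlignmentError(
            f"read {read.id!r} length {n} < 2 x seed length {mirna_index.seed_length}"
        )
    seq = read.sequence.encode("ascii")
    best: dict[tuple[int, int], tuple[int, int, np.ndarray]] = {}
    for t in range(max_nt_addition + 1):
        core = seq[: n - t]
        if len(core) < mirna_index.seed_length:
            break
        for ri, start, diff in _placements(core, mirna_index, max_internal_mismatch):
            key = (ri, start)
            cur = best.get(key)
            # t iterates ascending, so on equal mismatch counts the smaller
            # (templated) tail seen first is kept.
            if cur is None or len(diff) < len(cur[2]):
                best[key] = (t, len(core), diff)
    alns = [
        _to_alignment(read, mirna_index, ri, start, diff, core_len, t)
        for (ri, start), (t, core_len, diff) in best.items()
    ]
    alns.sort(key=lambda a: (a.ref_id, a.ref_start))
    return alns


def fractionate(alignments_of_one_read: Sequence[Alignment]) -> list[Alignment]:
    """Set multi-mapping weights: even split across all distinct references hit.

    A read mapping to k distinct reference records contributes 1/k to each —
    the fractionated count convention for multi-mapping reads.
    """
    if not alignments_of_one_read:
        raise AlignmentError("cannot fractionate an empty alignment list")
    read_ids = {a.read_id for a in alignments_of_one_read}
    if len(read_ids) != 1:
        raise AlignmentError("fractionate expects alignments of a single read")
    k = len({a.ref_id for a in alignments_of_one_read})
    return [replace(a, weight=1.0 / k) for a in alignments_of_one_read]


# ---------------------------------------------------------------------------
# optional dumps


def alignments_to_tsv(alignments: Sequence[Alignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tref_id\tref_start\tref_end\tsoft_tail_3p\tweight\tmismatches\n"
        )
        for a in alignments:
            mm = ";".join(
                f"{m.ref_position}:{m.ref_base}>{m.read_base}" for m in a.mismatches
            )
            fh.write(
                f"{a.read_id}\t{a.ref_id}\t{a.ref_start}\t{a.ref_end}\t"
                f"{a.soft_tail_3p}\t{a.weight:.6g}\t{mm}\n"
            )


def alignments_to_sam(
    alignments: Sequence[Alignment],
    index: ReferenceIndex,
    reads_by_id: dict[str, Read],
    path: str | Path,
) -> None:
    """Ungapped SAM dump with NM and MD tags (soft tails as soft clips)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for rec in index.records:
            fh.write(f"@SQ\tSN:{rec.id}\tLN:{rec.length}\n")
        for a in alignments:
            read = reads_by_id[a.read_id]
            cigar = f"{a.aligned_length}M"
            if a.soft_tail_3p:
                cigar += f"{a.soft_tail_3p}S"
            md, last = [], 0
            for m in sorted(a.mismatches, key=lambda m: m.ref_position):
                off = m.ref_position - a.ref_start
                md.append(f"{off - last}{m.ref_base}")
                last = off + 1
            md.append(str(a.aligned_length - last))
            fh.write(
                f"{a.read_id}\t0\t{a.ref_id}\t{a.ref_start}\t255\t{cigar}\t*\t0\t0\t"
                f"{read.sequence}\t*\tNM:i:{len(a.mismatches)}\tMD:Z:{''.join(md)}\n"
            )
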