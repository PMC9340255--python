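"""Adapter trimming and read filtering.

Reads are 3'-adapter trimmed, then reads shorter than 15 nt after trimming
are discarded (short inserts map ambiguously), and reads still containing the
5' adapter are discarded (a 5' adapter read-through can otherwise be
mis-annotated as a miRNA — the motivating case is hsa-miR-3168, which matches
part of the NEBNext 5' adapter).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

# NEBNext small RNA library kit adapters, shipped as config defaults.
NEB_3P_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
NEB_5P_ADAPTER = "GTTCAGAGTTCTACAGTCCGACGATC"

DEFAULT_MIN_LENGTH = 15
DEFAULT_MIN_OVERLAP = 3
DEFAULT_MAX_ERROR_RATE = 0.1


@dataclass(frozen=True)
class Read:
    """A sequencing read; qualities are optional and trimmed in lockstep."""

    id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PreprocessStats:
    """Partition accounting for one library: passed = input - short - 5' adapter."""

    input_reads: int = 0
    trimmed: int = 0
    discarded_short: int = 0
    discarded_5p_adapter: int = 0
    passed: int = 0

    def check(self) -> None:
        if self.passed != self.input_reads - self.discarded_short - self.discarded_5p_adapter:
            raise AssertionError(f"inconsistent preprocess stats: {self}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")


def _match_len(seq: str, pos: int, adapter: str, max_error_rate: float) -> int:
    """Length of the adapter-prefix match starting at seq[pos], 0 if none.

    The match extends to the read 3' end or the adapter end, whichever comes
    first (the adapter may overhang the read); accepted when the Hamming error
    rate over the compared length is <= max_error_rate.
    """
    n = min(len(seq) - pos, len(adapter))
    errors = sum(1 for i in range(n) if seq[pos + i] != adapter[i])
    return n if errors <= max_error_rate * n else 0


def trim_three_prime_adapter(
    read: Read,
    adapter: str = NEB_3P_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> Read:
    """Remove the leftmost 3' adapter occurrence and everything downstream.

    An occurrence is a prefix of ``adapter`` of length >= ``min_overlap``
    matching at or overhanging the read 3' end with Hamming error rate
    <= ``max_error_rate``.  A single pass removes the leftmost occurrence; no
    match returns the read unchanged.  Removal is deliberately not cascaded:
    an insert whose own last bases coincide with the adapter start by chance
    keeps them, instead of losing genuine sequence to repeated cutting.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must be in [0, 0.5)")
    seq = read.sequence
    for pos in range(len(seq) - min_overlap + 1):
        n = _match_len(seq, pos, adapter, max_error_rate)
        if n >= min_overlap:
            return Read(
                id=read.id,
                sequence=seq[:pos],
                qualities=read.qualities[:pos] if read.qualities is not None else None,
            )
    return read


DEFAULT_MIN_OVERLAP_5P = 8


def contains_five_prime_adapter(
    sequence: str,
    adapter: str = NEB_5P_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP_5P,
) -> bool:
    """Flag reads carrying 5' adapter sequence (adapter-dimer read-through).

    A read is flagged when it contains the full adapter, when the whole read
    is itself a substring of the adapter (the trimmed remnant of an
    adapter dimer), or when the read starts with an adapter suffix of length
    >= ``min_overlap``.  The overlap floor is deliberately longer than the 3'
    trimming overlap: a handful of adapter bases at a read boundary is
    indistinguishable from genuine small-RNA sequence, and a short floor would
    discard real reads at a rate of ~4^-k per boundary.
    """
    if adapter in sequence:
        return True
    if sequence and sequence in adapter:
        return True
    k = min(min_overlap, len(adapter))
    # adapter suffix at read start: sequencing began inside the 5' adapter
    for n in range(len(adapter) - 1, k - 1, -1):
        if sequence.startswith(adapter[-n:]):
            return True
    return False


def filter_reads(
    reads: Iterable[Read],
    min_length: int = DEFAULT_MIN_LENGTH,
    five_prime_adapter: str = NEB_5P_ADAPTER,
    three_prime_adapter: str = NEB_3P_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
    min_overlap_5p: int = DEFAULT_MIN_OVERLAP_5P,
) -> tuple[list[Read], PreprocessStats]:
    """Trim 3' adapters, then drop short and 5'-adapter-containing reads.

    The 5'-adapter test runs after trimming, on reads that already satisfy
    the length floor; the stats partition identity holds on every run.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    stats = PreprocessStats()
    out: list[Read] = []
    for read in reads:
        stats.input_reads += 1
        trimmed = trim_three_prime_adapter(
            read, three_prime_adapter, min_overlap, max_error_rate
        )
        if trimmed.length < read.length:
            stats.trimmed += 1
        if trimmed.length < min_length:
            stats.discarded_short += 1
            continue
        if contains_five_prime_adapter(trimmed.sequence, five_prime_adapter, min_overlap_5p):
            stats.discarded_5p_adapter += 1
            continue
        stats.passed += 1
        out.append(trimmed)
    stats.check()
    return out, stats


# ---------------------------------------------------------------------------
# FASTQ I/O (plain or gzip)


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a FASTQ file (optionally gzipped)."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip().upper()
            plus = fh.readline()
            qual = fh.readline().strip()
            if not qual and seq:
                raise ValueError(f"truncated FASTQ record at {header.strip()!r}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record at {header.strip()!r}")
            yield Read(id=header[1:].split()[0], sequence=seq, qualities=qual)


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.qualities if r.qualities is not None else "I" * r.length
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
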