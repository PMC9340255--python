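"""Tiered class assignment, fractionated counting and RPM normalization.

Reads are probed against reference tiers in priority order (miRNA first); the
first tier with any alignment claims the read and lower tiers are never
consulted.  Within the winning tier a multi-mapping read is fractionated
evenly across all references hit, and per-class/per-reference counts are
normalized to reads per million mapped reads (RPM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .mapper import Alignment, align_mirna, align_read, fractionate
from .preprocess import Read
from .references import ReferenceRecord, ReferenceTier


@dataclass
class AnnotatedRead:
    """A read's winning tier and its fractionated alignments within that tier."""

    read_id: str
    tier_rank: int
    rna_class: str
    alignments: list[Alignment]
    read_length: int
    sequence: str


def hierarchical_annotate(
    read: Read,
    tiers: Sequence[ReferenceTier],
    max_mismatch: int = 1,
    max_internal_mismatch: int = 1,
    max_nt_addition: int = 2,
) -> AnnotatedRead | None:
    """Assign a read to the highest-priority tier with at least one alignment.

    The miRNA tier is aligned in miRNA mode (non-templated 3' additions
    allowed); every other tier with exact full-length 1-mismatch alignment.
    Returns ``None`` for unmapped reads.
    """
    for tier in tiers:
        if "miRNA" in tier.classes:
            alns = align_mirna(
                read,
                tier.index,
                max_internal_mismatch=max_internal_mismatch,
                max_nt_addition=max_nt_addition,
            )
        else:
            alns = align_read(read, tier.index, max_mismatch=max_mismatch)
        if alns:
            alns = fractionate(alns)
            first_class = tier.index.by_id[alns[0].ref_id].rna_class
            return AnnotatedRead(
                read_id=read.id,
                tier_rank=tier.tier_rank,
                rna_class=first_class,
                alignments=alns,
                read_length=read.length,
                sequence=read.sequence,
            )
    return None


def annotate_library(
    reads: Iterable[Read], tiers: Sequence[ReferenceTier], **kwargs
) -> tuple[list[AnnotatedRead], int]:
    """Annotate a whole library; returns (annotated reads, unmapped count)."""
    annotated: list[AnnotatedRead] = []
    unmapped = 0
    for read in reads:
        ann = hierarchical_annotate(read, tiers, **kwargs)
        if ann is None:
            unmapped += 1
        else:
            annotated.append(ann)
    return annotated, unmapped


def count_table(
    annotated: Sequence[AnnotatedRead],
    records_by_id: dict[str, ReferenceRecord],
) -> pd.DataFrame:
    """Fractional counts per (rna_class, subclass, reference_id).

    Column ``fractional_count`` sums exactly to the number of mapped reads
    (each read's weights sum to 1 by construction).
    """
    rows: dict[tuple[str, str, str], float] = {}
    for ann in annotated:
        for aln in ann.alignments:
            rec = records_by_id[aln.ref_id]
            key = (rec.rna_class, rec.subclass, rec.id)
            rows[key] = rows.get(key, 0.0) + aln.weight
    df = pd.DataFrame(
        [(c, s, r, v) for (c, s, r), v in rows.items()],
        columns=["rna_class", "subclass", "reference_id", "fractional_count"],
    )
    return df.sort_values(["rna_class", "subclass", "reference_id"]).reset_index(drop=True)


def compute_rpm(table: pd.DataFrame) -> pd.DataFrame:
    """Add an ``rpm`` column: count / total mapped fractional count x 10^6."""
    total = table["fractional_count"].sum()
    if total <= 0:
        raise ValueError("zero mapped reads: RPM undefined")
    out = table.copy()
    out["rpm"] = out["fractional_count"] / total * 1e6
    return out


def class_fraction_summary(
    annotated: Sequence[AnnotatedRead],
    records_by_id: dict[str, ReferenceRecord],
) -> dict[str, float]:
    """Per-class percentage of mapped reads (fractional counts; sums to 100).

    Class attribution of a fractional read follows each alignment's record
    class, so a read split across tRNA and mt_tRNA references within one tier
    contributes its weights to both classes.
    """
    if not annotated:
        raise ValueError("no mapped reads")
    totals: dict[str, float] = {}
    grand = 0.0
    for ann in annotated:
        for aln in ann.alignments:
            cls = records_by_id[aln.ref_id].rna_class
            totals[cls] = totals.get(cls, 0.0) + aln.weight
            grand += aln.weight
    return {c: 100.0 * v / grand for c, v in sorted(totals.items())}
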