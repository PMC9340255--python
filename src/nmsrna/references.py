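"""Reference RNA sets: loading, validation, mature-tRNA construction and k-mer indexing.

The pipeline annotates reads against tiered reference sets (miRNA first, then
tRNA, rRNA, YRNA and the remaining small-RNA classes).  References are stored
in the DNA alphabet internally; U is transliterated to T at the FASTA boundary
so that reads and references compare directly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_CLASSES = frozenset(
    {
        "miRNA",
        "tRNA",
        "mt_tRNA",
        "rRNA",
        "mt_rRNA",
        "YRNA",
        "snoRNA",
        "snRNA",
        "lncRNA",
        "mRNA",
        "tRNA_trailer",
    }
)

_VALID_BASES = frozenset("ACGTN")


class ReferenceError(ValueError):
    """Invalid reference input (malformed FASTA, duplicate id, bad config)."""


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference RNA: identifier, class, subclass and DNA-alphabet sequence.

    ``subclass`` carries the field's grouping label: amino acid + anticodon
    for tRNAs (e.g. ``"Glu-TTC"``), the molecule name for rRNAs (``"28S"``),
    empty where no grouping applies.
    """

    id: str
    rna_class: str
    subclass: str
    sequence: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ReferenceError(f"unknown rna_class {self.rna_class!r} for {self.id!r}")
        if not self.sequence:
            raise ReferenceError(f"empty sequence for reference {self.id!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ReferenceError(
                f"reference {self.id!r} contains invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# header naming rules


def subclass_gtrnadb(header: str) -> str:
    """Extract ``AminoAcid-Anticodon`` from a gtRNAdb-style header.

    ``tRNA-Glu-TTC-1-1`` -> ``Glu-TTC``.  Falls back to the full header when
    the pattern is absent.
    """
    m = re.search(r"tRNA-([A-Za-z]{2,4}\d?-[A-Z]{3})", header)
    if m:
        return m.group(1)
    parts = header.split("-")
    if len(parts) >= 3:
        return "-".join(parts[1:3])
    return header


def subclass_first_token(header: str) -> str:
    """Use the first whitespace-delimited token of the header as subclass."""
    return header.split()[0] if header.split() else ""


def subclass_none(header: str) -> str:  # noqa: ARG001 - uniform signature
    return ""


SUBCLASS_PARSERS: dict[str, Callable[[str], str]] = {
    "gtrnadb": subclass_gtrnadb,
    "first_token": subclass_first_token,
    "none": subclass_none,
}


# ---------------------------------------------------------------------------
# FASTA I/O


def load_fasta(
    path: str | Path,
    rna_class: str,
    subclass_parser: str | Callable[[str], str] = "none",
) -> list[ReferenceRecord]:
    """Load one FASTA file into :class:`ReferenceRecord` objects.

    U is converted to T and the sequence is upper-cased; the subclass is
    extracted from the header by ``subclass_parser`` (a callable or one of the
    named rules in :data:`SUBCLASS_PARSERS`).  Duplicate identifiers raise
    :class:`ReferenceError`; an empty file yields an empty list with a warning.
    """
    if isinstance(subclass_parser, str):
        try:
            subclass_parser = SUBCLASS_PARSERS[subclass_parser]
        except KeyError as exc:
            raise ReferenceError(f"unknown subclass parser {subclass_parser!r}") from exc
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython's parse error carries position info
        raise ReferenceError(f"malformed FASTA {path}: {exc}") from exc
    for entry in parsed:
        if not entry.id:
            raise ReferenceError(f"malformed FASTA {path}: entry with empty header")
        if entry.id in seen:
            raise ReferenceError(f"duplicate reference id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = str(entry.seq).upper().replace("U", "T")
        records.append(
            ReferenceRecord(
                id=entry.id,
                rna_class=rna_class,
                subclass=subclass_parser(entry.description or entry.id),
                sequence=seq,
            )
        )
    if not records:
        logger.warning("FASTA %s contained no entries", path)
    return records


def write_fasta(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    """Write records back out as FASTA (DNA alphabet, one line per sequence)."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# mature tRNA / trailer construction


def build_mature_trna(
    spliced_gene_sequence: str,
    add_cca: bool = True,
    his_g_minus1: bool = False,
) -> str:
    """Build the mature tRNA body from a spliced gene sequence.

    3' fragments are defined on the mature molecule, which carries a
    post-transcriptionally added CCA tail (and, for tRNA-His, a G at
    position -1); reads ending "at the CCA end" only map if the reference
    includes it.  Appending is idempotent: a body already ending in CCA is
    left unchanged.
    """
    seq = spliced_gene_sequence.upper().replace("U", "T")
    if not seq:
        raise ReferenceError("empty tRNA body sequence")
    if his_g_minus1:
        seq = "G" + seq
    if add_cca and not seq.endswith("CCA"):
        seq = seq + "CCA"
    return seq


def build_trailer(downstream_genomic: str, max_length: int = 50) -> str:
    """Extract a precursor 3' trailer (tRF-1 source) from downstream genomic sequence.

    The trailer runs from the base after the discriminator to the RNA pol III
    terminator, modelled as the first run of >= 4 Ts, and is capped at
    ``max_length`` nt.
    """
    seq = downstream_genomic.upper().replace("U", "T")
    if not seq:
        raise ReferenceError("empty trailer input")
    m = re.search(r"TTTT", seq)
    if m:
        seq = seq[: m.start()]
    return seq[:max_length]


# ---------------------------------------------------------------------------
# k-mer seed index


@dataclass
class ReferenceIndex:
    """Exact k-mer seed index over a reference set.

    Every length-``seed_length`` substring of every record is a key in
    ``seed_table`` mapping to ``(record_index, offset)`` postings (offset
    0-based).  For any read of length >= 2 * seed_length placed on a record
    with at most one substitution, at least one of the read's two
    non-overlapping half seeds matches its source exactly (pigeonhole), so
    seed lookup is complete for 1-mismatch ungapped alignment.
    """

    records: list[ReferenceRecord]
    seed_length: int
    seed_table: dict[bytes, list[tuple[int, int]]] = field(repr=False)
    encoded: list[np.ndarray] = field(repr=False)
    by_id: dict[str, ReferenceRecord] = field(repr=False)


def build_reference_index(
    records: Sequence[ReferenceRecord], seed_length: int = 7
) -> ReferenceIndex:
    records = list(records)
    if not records:
        raise ReferenceError("cannot index an empty reference set")
    if seed_length < 1:
        raise ReferenceError("seed_length must be >= 1")
    shortest = min(r.length for r in records)
    if seed_length > shortest:
        raise ReferenceError(
            f"seed_length {seed_length} exceeds shortest record length {shortest}"
        )
    table: dict[bytes, list[tuple[int, int]]] = {}
    encoded: list[np.ndarray] = []
    for ri, rec in enumerate(records):
        raw = rec.sequence.encode("ascii")
        encoded.append(np.frombuffer(raw, dtype=np.uint8))
        for off in range(rec.length - seed_length + 1):
            table.setdefault(raw[off : off + seed_length], []).append((ri, off))
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ReferenceError("duplicate reference ids in index input")
    return ReferenceIndex(
        records=records,
        seed_length=seed_length,
        seed_table=table,
        encoded=encoded,
        by_id=by_id,
    )


@dataclass
class ReferenceTier:
    """One priority tier: rank 1 is probed first; ties within a tier fractionate."""

    tier_rank: int
    classes: frozenset[str]
    records: list[ReferenceRecord]
    index: ReferenceIndex = field(repr=False)


DEFAULT_TIER_ORDER: tuple[frozenset[str], ...] = (
    frozenset({"miRNA"}),
    frozenset({"tRNA", "mt_tRNA", "tRNA_trailer"}),
    frozenset({"rRNA", "mt_rRNA"}),
    frozenset({"YRNA"}),
    frozenset({"snoRNA"}),
    frozenset({"snRNA"}),
    frozenset({"lncRNA"}),
    frozenset({"mRNA"}),
)


def build_tiers(
    records: Iterable[ReferenceRecord],
    tier_order: Sequence[Iterable[str]] = DEFAULT_TIER_ORDER,
    seed_length: int = 7,
) -> list[ReferenceTier]:
    """Group records into priority tiers and index each tier.

    Tiers whose classes have no records are dropped; ranks are renumbered to
    stay contiguous from 1.
    """
    pool = list(records)
    tiers: list[ReferenceTier] = []
    rank = 1
    for classes in tier_order:
        classes = frozenset(classes)
        members = [r for r in pool if r.rna_class in classes]
        if not members:
            continue
        tiers.append(
            ReferenceTier(
                tier_rank=rank,
                classes=classes,
                records=members,
                index=build_reference_index(members, seed_length=seed_length),
            )
        )
        rank += 1
    return tiers


def load_reference_manifest(manifest: Mapping | str | Path) -> list[ReferenceTier]:
    """Load a reference manifest (YAML/JSON-style mapping or path to YAML file).

    Expected shape::

        seed_length: 7
        tier_order: [[miRNA], [tRNA, mt_tRNA, tRNA_trailer], ...]   # optional
        sets:
          - {path: mirnas.fa, rna_class: miRNA, subclass_parser: none}
          - {path: trnas.fa, rna_class: tRNA, subclass_parser: gtrnadb}
    """
    if isinstance(manifest, (str, Path)):
        import yaml

        with open(manifest) as fh:
            manifest = yaml.safe_load(fh)
    records: list[ReferenceRecord] = []
    for entry in manifest["sets"]:
        records.extend(
            load_fasta(
                entry["path"],
                entry["rna_class"],
                entry.get("subclass_parser", "none"),
            )
        )
    tier_order = manifest.get("tier_order") or DEFAULT_TIER_ORDER
    return build_tiers(
        records,
        tier_order=[frozenset(t) for t in tier_order],
        seed_length=int(manifest.get("seed_length", 7)),
    )
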