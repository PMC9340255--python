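"""Fragment subtype taxonomy, size distributions and the Argonaute-size filter.

tRNA-derived fragments (tRFs) are named by where they sit on the mature tRNA:
5'-anchored fragments (tRF-5a/b/c and the anticodon-loop-cleaved 5' half,
tiR-5), 3'-anchored fragments ending at the CCA tail (tRF-3a/b and the 3'
half, tiR-3), and tRF-1s transcribed from the precursor 3' trailer.  Length
cut-points between the series members follow the dominant sizes observed in
TGIRT libraries (5' series 32-34 / 27 / 19 nt; 3' series 37-38 / 22 / 18 nt)
and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotate import AnnotatedRead
from .mapper import Alignment
from .references import ReferenceRecord

TRF_SUBTYPES = (
    "tiR-5",
    "tRF-5c",
    "tRF-5b",
    "tRF-5a",
    "tiR-3",
    "tRF-3b",
    "tRF-3a",
    "tRF-1",
    "internal",
)

TRNA_CLASSES = frozenset({"tRNA", "mt_tRNA", "tRNA_trailer"})


@dataclass(frozen=True)
class TrfBoundaries:
    """Length cut-points for the 5' and 3' tRF series (inclusive bounds)."""

    half_min: int = 30        # >= half_min -> tiR (tRNA half)
    trf5c_min: int = 27       # 27-29 -> tRF-5c
    trf5b_min: int = 23       # 23-26 -> tRF-5b; <= 22 -> tRF-5a
    trf3b_min: int = 20       # 20-29 -> tRF-3b; <= 19 -> tRF-3a


DEFAULT_BOUNDARIES = TrfBoundaries()


def classify_trf(
    aln: Alignment,
    ref: ReferenceRecord,
    tol5: int = 1,
    tol3: int = 1,
    boundaries: TrfBoundaries = DEFAULT_BOUNDARIES,
) -> str:
    """Subtype of one tRNA-class alignment, from its coordinates alone.

    Trailer records always yield tRF-1.  On mature tRNAs, an alignment
    starting within ``tol5`` of position 1 is a 5'-series fragment and one
    ending within ``tol3`` of the CCA end is 3'-series, each bucketed by
    aligned length; anything else is internal.
    """
    if ref.rna_class not in TRNA_CLASSES:
        raise ValueError(f"classify_trf requires a tRNA-class record, got {ref.rna_class}")
    if ref.rna_class == "tRNA_trailer":
        return "tRF-1"
    length = aln.aligned_length
    b = boundaries
    if aln.ref_start <= 1 + tol5:
        if length >= b.half_min:
            return "tiR-5"
        if length >= b.trf5c_min:
            return "tRF-5c"
        if length >= b.trf5b_min:
            return "tRF-5b"
        return "tRF-5a"
    if aln.ref_end >= ref.length - tol3:
        if length >= b.half_min:
            return "tiR-3"
        if length >= b.trf3b_min:
            return "tRF-3b"
        return "tRF-3a"
    return "internal"


TRF_SERIES = {
    "tiR-5": "5p",
    "tRF-5a": "5p",
    "tRF-5b": "5p",
    "tRF-5c": "5p",
    "tiR-3": "3p",
    "tRF-3a": "3p",
    "tRF-3b": "3p",
    "tRF-1": "tRF-1",
    "internal": "internal",
}


def size_histograms(
    annotated: Sequence[AnnotatedRead],
    records_by_id: dict[str, ReferenceRecord],
    tol5: int = 1,
    tol3: int = 1,
    boundaries: TrfBoundaries = DEFAULT_BOUNDARIES,
) -> pd.DataFrame:
    """Length histograms in RPM per class and, for tRNA classes, per tRF subtype.

    Rows: (rna_class, subtype, length, fractional_count, rpm); subtype is ""
    for non-tRNA classes.  Summing rpm over lengths within a class returns the
    class RPM; summing everything returns 10^6.
    """
    rows: dict[tuple[str, str, int], float] = {}
    total = 0.0
    for ann in annotated:
        for aln in ann.alignments:
            rec = records_by_id[aln.ref_id]
            sub = (
                classify_trf(aln, rec, tol5, tol3, boundaries)
                if rec.rna_class in TRNA_CLASSES
                else ""
            )
            key = (rec.rna_class, sub, ann.read_length)
            rows[key] = rows.get(key, 0.0) + aln.weight
            total += aln.weight
    if total <= 0:
        raise ValueError("no mapped reads")
    df = pd.DataFrame(
        [(c, s, ln, v, v / total * 1e6) for (c, s, ln), v in rows.items()],
        columns=["rna_class", "subtype", "length", "fractional_count", "rpm"],
    )
    return df.sort_values(["rna_class", "subtype", "length"]).reset_index(drop=True)


def modal_lengths(histograms: pd.DataFrame, by_subtype: bool = False) -> dict[str, int]:
    """Modal read length per class (or per tRF subtype when ``by_subtype``)."""
    key = "subtype" if by_subtype else "rna_class"
    frame = histograms[histograms["subtype"] != ""] if by_subtype else histograms
    modes: dict[str, int] = {}
    for name, grp in frame.groupby(key):
        agg = grp.groupby("length")["rpm"].sum()
        modes[str(name)] = int(agg.idxmax())
    return modes


@dataclass(frozen=True)
class AgoCandidate:
    """A miRNA-sized non-miRNA sequence abundant enough to enter Argonaute."""

    sequence: str
    mean_rpm: float
    n_samples_detected: int
    per_sample_rpm: tuple[float, ...]


def sequence_rpm_table(
    annotated: Sequence[AnnotatedRead],
    records_by_id: dict[str, ReferenceRecord],
    exclude_classes: frozenset[str] = frozenset({"miRNA"}),
) -> pd.DataFrame:
    """Per unique read sequence: fractional count and RPM, non-miRNA reads only.

    RPM is normalized by ALL mapped reads of the sample (miRNA included), so
    abundances are comparable with miRNA RPMs.
    """
    total = 0.0
    per_seq: dict[str, float] = {}
    for ann in annotated:
        w = sum(a.weight for a in ann.alignments)
        total += w
        cls = {records_by_id[a.ref_id].rna_class for a in ann.alignments}
        if cls & exclude_classes:
            continue
        per_seq[ann.sequence] = per_seq.get(ann.sequence, 0.0) + w
    if total <= 0:
        raise ValueError("no mapped reads")
    return pd.DataFrame(
        [(s, v, v / total * 1e6) for s, v in per_seq.items()],
        columns=["sequence", "fractional_count", "rpm"],
    )


def select_ago_candidates(
    per_sample_tables: Sequence[pd.DataFrame],
    min_len: int = 18,
    max_len: int = 24,
    min_samples: int = 10,
    rpm_low: float = 500.0,
    rpm_high: float = 15000.0,
) -> list[AgoCandidate]:
    """Argonaute-candidate filter over per-sample sequence RPM tables.

    Keeps unique non-miRNA sequences that are 18-24 nt (the miRNA size range
    loaded by Argonaute), detected (RPM > 0) in at least ``min_samples``
    samples, and whose mean RPM across samples falls in [rpm_low, rpm_high]
    (miRNA-comparable abundance).  Sorted by mean RPM, descending.
    """
    if not per_sample_tables:
        raise ValueError("at least one sample table required")
    n = len(per_sample_tables)
    rpm: dict[str, list[float]] = {}
    for i, tbl in enumerate(per_sample_tables):
        for seq, val in zip(tbl["sequence"], tbl["rpm"]):
            if not (min_len <= len(seq) <= max_len):
                continue
            rpm.setdefault(seq, [0.0] * n)[i] = float(val)
    out = []
    for seq, vec in rpm.items():
        detected = sum(1 for v in vec if v > 0)
        mean = sum(vec) / n
        if detected >= min_samples and rpm_low <= mean <= rpm_high:
            out.append(
                AgoCandidate(
                    sequence=seq,
                    mean_rpm=mean,
                    n_samples_detected=detected,
                    per_sample_rpm=tuple(vec),
                )
            )
    out.sort(key=lambda c: (-c.mean_rpm, c.sequence))
    return out
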