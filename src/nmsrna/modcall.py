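"""Per-position coverage, mismatch index and canonical modification-site reports.

TGIRT reads through Watson-Crick-face base modifications (m1A, m1G, m2,2G,
m3U, m1acp3-pseudouridine) and leaves a misincorporation instead of a hard
stop.  The per-position *mismatch index* — the percentage of covering reads
carrying a substitution at that position, 0-100 — is therefore a proxy for
the modification level at that position.  Profiles from tRNA-derived
fragments are aggregated by amino-acid group, anchored either at the 5' end
(sites 9, 26) or at the 3' CCA end (site 58, whose distance from the 3' end
is nearly invariant across tRNA lengths because the T-loop abuts the acceptor
stem).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedRead
from .fragments import TRF_SERIES, TRNA_CLASSES, classify_trf
from .mapper import Alignment
from .references import ReferenceRecord


@dataclass
class CoverageProfile:
    """Per-position fractional depth and per-substitution mismatch mass."""

    ref_id: str
    length: int
    depth: np.ndarray
    mm: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def mismatch_mass(self) -> np.ndarray:
        """Total mismatch mass per position, summed over substitution types."""
        out = np.zeros(self.length)
        for arr in self.mm.values():
            out += arr
        return out

    def check(self) -> None:
        mass = self.mismatch_mass()
        if np.any(self.depth < -1e-9):
            raise AssertionError("negative depth")
        if np.any(mass > self.depth + 1e-9):
            raise AssertionError("mismatch mass exceeds depth")


def build_coverage(
    alignments: Iterable[Alignment], ref_id: str, ref_length: int
) -> CoverageProfile:
    """Pile up fractional alignment weights along one reference.

    depth[p] sums the weights of alignments spanning p; mm[(ref, read)][p]
    sums the weights of alignments recording that substitution at p.  A read
    counts once at its mismatch position regardless of substitution identity
    (reads, not bases, are the numerator unit).  Soft-tail bases of miRNA-mode
    alignments are not aligned and contribute nothing.
    """
    prof = CoverageProfile(ref_id=ref_id, length=ref_length, depth=np.zeros(ref_length))
    for aln in alignments:
        if aln.ref_id != ref_id:
            raise ValueError(f"alignment on {aln.ref_id!r}, expected {ref_id!r}")
        if aln.ref_start < 1 or aln.ref_end > ref_length:
            raise ValueError(
                f"alignment {aln.ref_start}-{aln.ref_end} out of bounds for "
                f"{ref_id!r} (length {ref_length})"
            )
        prof.depth[aln.ref_start - 1 : aln.ref_end] += aln.weight
        for m in aln.mismatches:
            key = (m.ref_base, m.read_base)
            if key not in prof.mm:
                prof.mm[key] = np.zeros(ref_length)
            prof.mm[key][m.ref_position - 1] += aln.weight
    return prof


def mismatch_index(
    profile: CoverageProfile, position: int, min_coverage: float = 1.0
) -> float | None:
    """Mismatch index at a 1-based position: 100 x mismatch mass / depth.

    ``None`` when depth is below ``min_coverage`` (rendered as missing — no
    call can be made without coverage).
    """
    if not 1 <= position <= profile.length:
        raise ValueError(f"position {position} outside 1..{profile.length}")
    d = profile.depth[position - 1]
    if d < min_coverage or d <= 0:
        return None
    mass = sum(arr[position - 1] for arr in profile.mm.values())
    return float(100.0 * mass / d)


def mismatch_index_track(
    profile: CoverageProfile, min_coverage: float = 1.0
) -> np.ndarray:
    """Whole-reference mismatch-index track; NaN where coverage is below floor."""
    with np.errstate(divide="ignore", invalid="ignore"):
        track = 100.0 * profile.mismatch_mass() / profile.depth
    track[profile.depth < min_coverage] = np.nan
    return track


def aggregate_trf_profiles(
    profiles: Mapping[str, CoverageProfile],
    records_by_id: dict[str, ReferenceRecord],
    grouping: str = "amino_acid",
    anchor: str = "five_prime",
) -> dict[str, CoverageProfile]:
    """Sum per-isodecoder tRNA profiles into per-group profiles.

    ``grouping`` is "amino_acid" (subclass before the dash, e.g. Glu) or
    "isoacceptor" (full subclass, e.g. Glu-TTC).  Each group profile has the
    length of its longest member; with ``anchor="five_prime"`` members co-add
    from position 1, with ``anchor="three_prime"`` from the 3' terminal base
    (the CCA end), shorter members contributing nothing beyond their extent.
    """
    if anchor not in {"five_prime", "three_prime"}:
        raise ValueError(f"unknown anchor {anchor!r}")
    groups: dict[str, list[CoverageProfile]] = {}
    for ref_id, prof in profiles.items():
        rec = records_by_id[ref_id]
        if rec.rna_class not in {"tRNA", "mt_tRNA"}:
            raise ValueError(f"aggregation requires tRNA-class profiles, got {rec.rna_class}")
        key = rec.subclass.split("-")[0] if grouping == "amino_acid" else rec.subclass
        groups.setdefault(key, []).append(prof)
    out: dict[str, CoverageProfile] = {}
    for key, members in groups.items():
        glen = max(p.length for p in members)
        agg = CoverageProfile(ref_id=key, length=glen, depth=np.zeros(glen))
        for p in members:
            if anchor == "five_prime":
                sl = slice(0, p.length)
            else:
                sl = slice(glen - p.length, glen)
            agg.depth[sl] += p.depth
            for mk, arr in p.mm.items():
                if mk not in agg.mm:
                    agg.mm[mk] = np.zeros(glen)
                agg.mm[mk][sl] += arr
        out[key] = agg
    return out


@dataclass(frozen=True)
class CanonicalSite:
    """A known modification site: label, anchoring rule and expected modification.

    ``offset`` is 1-based from the 5' end for ``five_prime`` and ``absolute``
    anchoring; for ``three_prime`` it counts bases upstream of the 3' terminal
    base (offset 18 on a 76-nt tRNA is position 58).
    """

    label: str
    anchoring: str  # five_prime | three_prime | absolute
    offset: int
    ref_or_group: str
    expected_modification: str


CANONICAL_SITES: tuple[CanonicalSite, ...] = (
    CanonicalSite("tRNA:9", "five_prime", 9, "tRNA", "m1G/m1A"),
    CanonicalSite("tRNA:26", "five_prime", 26, "tRNA", "m2,2G"),
    CanonicalSite("tRNA:58", "three_prime", 18, "tRNA", "m1A"),
    CanonicalSite("28S:1322", "absolute", 1322, "28S", "m1A"),
    CanonicalSite("28S:4530", "absolute", 4530, "28S", "m3U"),
    CanonicalSite("18S:1248", "absolute", 1248, "18S", "m1acp3Y"),
)


def resolve_site_position(site: CanonicalSite, profile_length: int) -> int:
    """1-based position of a canonical site on a profile of the given length."""
    if site.anchoring in {"five_prime", "absolute"}:
        pos = site.offset
    elif site.anchoring == "three_prime":
        pos = profile_length - site.offset
    else:
        raise ValueError(f"unknown anchoring {site.anchoring!r}")
    if not 1 <= pos <= profile_length:
        raise ValueError(
            f"site {site.label} resolves to position {pos} outside profile "
            f"of length {profile_length}"
        )
    return pos


def site_report(
    profiles_per_sample: Mapping[str, Mapping[str, Mapping[str, CoverageProfile]]],
    sites: Sequence[CanonicalSite] = CANONICAL_SITES,
    min_coverage: float = 10.0,
) -> pd.DataFrame:
    """Mismatch index at canonical sites, per sample x profile group.

    Each sample maps kind -> group -> profile, where kind is
    "tRNA_five_prime" / "tRNA_three_prime" (amino-acid group profiles from
    :func:`aggregate_trf_profiles` under the matching anchor) or "rRNA"
    (per-molecule profiles keyed by molecule name, e.g. "28S").  tRNA sites
    are evaluated on every tRNA group under their own anchoring (5'-anchored
    offsets 9 and 26; 3'-anchored site 58); absolute rRNA sites only on the
    matching molecule.
    Cells without ``min_coverage`` depth are null (no call).  Columns:
    sample, site, group, expected_modification, position, depth,
    mismatch_index.
    """
    rows = []
    for sample, kinds in profiles_per_sample.items():
        for site in sites:
            if site.anchoring == "absolute":
                pool = {
                    gid: prof
                    for gid, prof in kinds.get("rRNA", {}).items()
                    if gid == site.ref_or_group or gid.startswith(site.ref_or_group)
                }
            else:
                pool = dict(kinds.get(f"tRNA_{site.anchoring}", kinds.get("tRNA", {})))
                if site.ref_or_group != "tRNA":
                    pool = {g: p for g, p in pool.items() if g == site.ref_or_group}
            for gid, prof in pool.items():
                try:
                    pos: int | None = resolve_site_position(site, prof.length)
                except ValueError:
                    pos, depth, idx = None, 0.0, None
                else:
                    depth = float(prof.depth[pos - 1])
                    idx = mismatch_index(prof, pos, min_coverage=min_coverage)
                rows.append(
                    (sample, site.label, gid, site.expected_modification, pos, depth, idx)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "site",
            "group",
            "expected_modification",
            "position",
            "depth",
            "mismatch_index",
        ],
    )


def mismatch_type_fractions(
    annotated: Sequence[AnnotatedRead],
    records_by_id: dict[str, ReferenceRecord],
    tol5: int = 1,
    tol3: int = 1,
) -> pd.DataFrame:
    """Fraction of reads carrying a mismatch, by category and reference base.

    Categories are the rna_class, with tRNA-class reads split into the tRF
    5'/3' series (and tRF-1/internal).  A read's category and mismatch are
    taken per alignment with its fractional weight; fractions are in [0, 1]
    and keyed by the REFERENCE base (an "A-type" mismatch is A -> C/G/T).
    Columns: category, ref_base, fraction, total_weight.
    """
    denom: dict[str, float] = {}
    numer: dict[tuple[str, str], float] = {}
    for ann in annotated:
        for aln in ann.alignments:
            rec = records_by_id[aln.ref_id]
            if rec.rna_class in TRNA_CLASSES:
                series = TRF_SERIES[classify_trf(aln, rec, tol5, tol3)]
                cat = f"tRF-{series}" if series in {"5p", "3p"} else series
            else:
                cat = rec.rna_class
            denom[cat] = denom.get(cat, 0.0) + aln.weight
            for base in {m.ref_base for m in aln.mismatches}:
                numer[(cat, base)] = numer.get((cat, base), 0.0) + aln.weight
    rows = []
    for cat, tot in sorted(denom.items()):
        for base in "ACGT":
            frac = numer.get((cat, base), 0.0) / tot if tot > 0 else np.nan
            rows.append((cat, base, frac, tot))
    return pd.DataFrame(rows, columns=["category", "ref_base", "fraction", "total_weight"])


def profiles_from_annotated(
    annotated: Sequence[AnnotatedRead],
    records_by_id: dict[str, ReferenceRecord],
    classes: frozenset[str] | None = None,
) -> dict[str, CoverageProfile]:
    """Build per-reference coverage profiles from annotated reads.

    ``classes`` restricts to the given rna_classes (e.g. tRNA only); by
    default all references with any alignment get a profile.
    """
    by_ref: dict[str, list[Alignment]] = {}
    for ann in annotated:
        for aln in ann.alignments:
            rec = records_by_id[aln.ref_id]
            if classes is not None and rec.rna_class not in classes:
                continue
            by_ref.setdefault(aln.ref_id, []).append(aln)
    return {
        rid: build_coverage(alns, rid, records_by_id[rid].length)
        for rid, alns in by_ref.items()
    }
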