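"""Synthetic reference set for tests, simulation and demos.

Real patient libraries and the full miRBase/gtRNAdb/Ensembl reference sets
are not required anywhere in this package: this module builds a small
synthetic-but-realistic reference set — a few 76-nt mature tRNAs per
amino-acid group (CCA-ended, G9/G26 and a T-loop A at the position-58
equivalent), rRNA surrogates long enough to carry the canonical modification
sites at their literal coordinates (28S-like: 1322 and 4530; 18S-like: 1248),
four YRNA analogues with terminal-stem/preterminal-loop dot-bracket
structures, trailer records for tRF-1s, and ten miRNA-like 22-mers.  All
sequences are synthetic (fixed internal seed) and every identifier is suffixed
``_syn``; real reference FASTAs are drop-in replacements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .references import ReferenceRecord
from .ystructure import SecondaryStructure, parse_dot_bracket

_FIXTURE_SEED = 20240901
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _with_bases(seq: str, assignments: dict[int, str]) -> str:
    """Force specific bases at 1-based positions."""
    chars = list(seq)
    for pos, base in assignments.items():
        chars[pos - 1] = base
    return "".join(chars)


def _pair_structure(seq: str, structure: SecondaryStructure) -> str:
    """Make paired positions Watson-Crick complementary (downstream partner set)."""
    chars = list(seq)
    for i, j in enumerate(structure.paired_with, start=1):
        if j is not None and j > i:
            chars[j - 1] = _COMPLEMENT[chars[i - 1]]
    return "".join(chars)


# YRNA analogue geometry: (length, dot-bracket, default cleavage position).
# A 20-bp terminal stem (5' and 3' ends annealed), one internal hairpin, and
# an unpaired preterminal loop abutting the stem's 3' arm, where the default
# cleavage position sits.  Cleavage positions give dominant 3' fragments of
# 33 / 35 / 31 / 33 nt.
_YRNA_GEOMETRY: dict[str, tuple[int, str, int]] = {
    "RNY5_syn": (
        83,
        "(" * 20 + "...." + "((((((" + "....." + "))))))" + "." * 22 + ")" * 20,
        50,
    ),
    "RNY4_syn": (
        96,
        "(" * 20 + "." * 8 + "((((((" + "." * 6 + "))))))" + "." * 30 + ")" * 20,
        61,
    ),
    "RNY1_syn": (
        100,
        "(" * 20 + "." * 8 + "((((((" + "." * 8 + "))))))" + "." * 32 + ")" * 20,
        69,
    ),
    "RNY3_syn": (
        90,
        "(" * 20 + "." * 6 + "((((((" + "." * 6 + "))))))" + "." * 26 + ")" * 20,
        57,
    ),
}

DEFAULT_YRF_CLEAVAGE: dict[str, int] = {k: v[2] for k, v in _YRNA_GEOMETRY.items()}

# tRNA bodies: 76 nt including the CCA end; position 58 == length - 18.
_TRNA_SUBCLASSES = ("Glu-TTC", "Gly-GCC", "Leu-AAG", "Arg-TCT", "Asp-GTC", "Ser-TGA")


@dataclass
class FixtureReferenceSet:
    """The bundled synthetic reference set plus YRNA structures."""

    records: list[ReferenceRecord]
    structures: dict[str, SecondaryStructure] = field(default_factory=dict)

    @property
    def by_id(self) -> dict[str, ReferenceRecord]:
        return {r.id: r for r in self.records}

    def by_class(self, rna_class: str) -> list[ReferenceRecord]:
        return [r for r in self.records if r.rna_class == rna_class]


def fixture_reference_set() -> FixtureReferenceSet:
    """Build the deterministic synthetic reference set (~25 records)."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    records: list[ReferenceRecord] = []

    # mature tRNAs: G9 (A9 on the Asp analogue), G26, A at the position-58
    # equivalent (18 nt upstream of the CCA 3' end), CCA-terminated
    for sub in _TRNA_SUBCLASSES:
        seq = _random_seq(rng, 73)
        seq = _with_bases(seq, {9: "A" if sub.startswith("Asp") else "G", 26: "G", 58: "A"})
        seq = seq[:73] + "CCA"
        records.append(
            ReferenceRecord(id=f"tRNA-{sub}-syn1", rna_class="tRNA", subclass=sub, sequence=seq)
        )

    # mitochondrial tRNAs (72 nt, same landmark layout relative to the 3' end)
    for sub in ("Glu-TTC", "Lys-TTT"):
        seq = _random_seq(rng, 69)
        seq = _with_bases(seq, {9: "G", 26: "G", 72 - 18: "A"})
        seq = seq + "CCA"
        records.append(
            ReferenceRecord(
                id=f"mt-tRNA-{sub}-syn1", rna_class="mt_tRNA", subclass=sub, sequence=seq
            )
        )

    # precursor 3' trailer (tRF-1 source) for the Ser analogue
    trailer = _random_seq(rng, 25).replace("TTTT", "TTAT")
    records.append(
        ReferenceRecord(
            id="tRNA-Ser-TGA-syn1_trailer",
            rna_class="tRNA_trailer",
            subclass="Ser-TGA",
            sequence=trailer,
        )
    )

    # rRNA surrogates: long enough that the canonical sites sit at their
    # literal 1-based coordinates (m1A 28S:1322, m3U 28S:4530, m1acp3Y 18S:1248)
    s28 = _with_bases(_random_seq(rng, 4600), {1322: "A", 4530: "T"})
    s18 = _with_bases(_random_seq(rng, 1900), {1248: "T"})
    records.append(ReferenceRecord(id="28S_syn", rna_class="rRNA", subclass="28S", sequence=s28))
    records.append(ReferenceRecord(id="18S_syn", rna_class="rRNA", subclass="18S", sequence=s18))
    records.append(
        ReferenceRecord(id="5.8S_syn", rna_class="rRNA", subclass="5.8S", sequence=_random_seq(rng, 157))
    )
    records.append(
        ReferenceRecord(id="5S_syn", rna_class="rRNA", subclass="5S", sequence=_random_seq(rng, 121))
    )
    records.append(
        ReferenceRecord(
            id="mt16S_syn", rna_class="mt_rRNA", subclass="mt16S", sequence=_random_seq(rng, 950)
        )
    )

    # YRNA analogues with annealing 5'/3' terminal stems
    structures: dict[str, SecondaryStructure] = {}
    for yid, (length, db, _c) in _YRNA_GEOMETRY.items():
        struct = parse_dot_bracket(db, ref_id=yid)
        assert struct.length == length
        seq = _pair_structure(_random_seq(rng, length), struct)
        records.append(
            ReferenceRecord(id=yid, rna_class="YRNA", subclass=yid.split("_")[0], sequence=seq)
        )
        structures[yid] = struct

    # miRNA-like 22-mers
    for i in range(1, 11):
        records.append(
            ReferenceRecord(
                id=f"mir-syn-{i}", rna_class="miRNA", subclass="", sequence=_random_seq(rng, 22)
            )
        )

    # remaining classes (fragment sources for the "other" mixture slice)
    records.append(
        ReferenceRecord(id="snoRNA-syn-1", rna_class="snoRNA", subclass="", sequence=_random_seq(rng, 100))
    )
    records.append(
        ReferenceRecord(id="snoRNA-syn-2", rna_class="snoRNA", subclass="", sequence=_random_seq(rng, 80))
    )
    records.append(
        ReferenceRecord(id="snRNA-syn-1", rna_class="snRNA", subclass="", sequence=_random_seq(rng, 110))
    )
    records.append(
        ReferenceRecord(id="lncRNA-syn-1", rna_class="lncRNA", subclass="", sequence=_random_seq(rng, 400))
    )
    records.append(
        ReferenceRecord(id="mRNA-syn-1", rna_class="mRNA", subclass="", sequence=_random_seq(rng, 600))
    )
    return FixtureReferenceSet(records=records, structures=structures)
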