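"""YRNA secondary-structure coverage and cleavage-site detection.

YRNAs fold into a long terminal stem (the 5' and 3' ends anneal) flanked by
single-stranded loops; the loop adjacent to the terminal stem is the
*preterminal loop*, where YRNA-fragment (YRF) cleavage concentrates.  This
module parses dot-bracket structures, normalizes per-base YRF coverage to the
YRNA's maximum, and reports coverage-drop positions annotated by pairing
state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .modcall import CoverageProfile


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class SecondaryStructure:
    """Dot-bracket structure with a symmetric partner map (1-based, None = unpaired)."""

    ref_id: str
    dot_bracket: str
    paired_with: tuple[int | None, ...]

    @property
    def length(self) -> int:
        return len(self.dot_bracket)

    def is_paired(self, position: int) -> bool:
        return self.paired_with[position - 1] is not None


def parse_dot_bracket(text: str, ref_id: str = "") -> SecondaryStructure:
    """Parse a dot-bracket string into a partner map.

    Unbalanced brackets raise :class:`StructureError` naming the 1-based
    offending position.
    """
    text = text.strip()
    if not text:
        raise StructureError("empty dot-bracket string")
    bad = set(text) - set(".()")
    if bad:
        raise StructureError(f"invalid dot-bracket characters {sorted(bad)}")
    partners: list[int | None] = [None] * len(text)
    stack: list[int] = []
    for i, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {i}")
            j = stack.pop()
            partners[i - 1] = j
            partners[j - 1] = i
    if stack:
        raise StructureError(f"unclosed '(' at position {stack[-1]}")
    return SecondaryStructure(ref_id=ref_id, dot_bracket=text, paired_with=tuple(partners))


def load_dot_bracket_file(path) -> dict[str, SecondaryStructure]:
    """Read a Vienna/Rfam-style file: >id / sequence (optional) / dot-bracket lines."""
    structures: dict[str, SecondaryStructure] = {}
    name, lines = None, []
    def flush():
        if name is None:
            return
        db = next((ln for ln in lines if set(ln) <= set(".()")), None)
        if db is None:
            raise StructureError(f"no dot-bracket line for {name!r}")
        structures[name] = parse_dot_bracket(db, ref_id=name)
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, lines = line[1:].split()[0], []
            else:
                lines.append(line.split()[0])
        flush()
    return structures


@dataclass
class StructureCoverage:
    """Coverage normalized to the YRNA's maximum, with detected cleavage sites."""

    ref_id: str
    normalized: np.ndarray
    cleavage_sites: list["CleavageSite"]


@dataclass(frozen=True)
class CleavageSite:
    """A coverage step between positions p and p+1 (1-based p), with pairing state."""

    position: int
    drop: float
    region: str  # "paired" | "unpaired"


def normalized_structure_coverage(
    profile: CoverageProfile, structure: SecondaryStructure
) -> np.ndarray:
    """Per-base coverage divided by the maximum coverage on this YRNA.

    All zeros when there is no coverage (no division error); idempotent when
    reapplied.
    """
    if profile.length != structure.length:
        raise StructureError(
            f"profile length {profile.length} != structure length {structure.length}"
        )
    peak = float(profile.depth.max()) if profile.length else 0.0
    if peak <= 0:
        return np.zeros(profile.length)
    return profile.depth / peak


def detect_cleavage_sites(
    profile: CoverageProfile,
    structure: SecondaryStructure,
    min_drop_fraction: float = 0.5,
) -> list[CleavageSite]:
    """Positions where coverage steps by at least ``min_drop_fraction`` of the peak.

    A site is the 1-based position p with |depth[p+1] - depth[p]| >= threshold,
    annotated with whether p lies in a paired (stem) or unpaired (loop) region;
    sorted by drop magnitude, descending.
    """
    if profile.length != structure.length:
        raise StructureError(
            f"profile length {profile.length} != structure length {structure.length}"
        )
    peak = float(profile.depth.max()) if profile.length else 0.0
    if peak <= 0:
        return []
    threshold = min_drop_fraction * peak
    sites = []
    steps = np.diff(profile.depth)
    for p0 in np.nonzero(np.abs(steps) >= threshold)[0]:
        pos = int(p0) + 1
        sites.append(
            CleavageSite(
                position=pos,
                drop=float(abs(steps[p0])),
                region="paired" if structure.is_paired(pos) else "unpaired",
            )
        )
    sites.sort(key=lambda s: (-s.drop, s.position))
    return sites


def structure_coverage(
    profile: CoverageProfile,
    structure: SecondaryStructure,
    min_drop_fraction: float = 0.5,
) -> StructureCoverage:
    return StructureCoverage(
        ref_id=structure.ref_id or profile.ref_id,
        normalized=normalized_structure_coverage(profile, structure),
        cleavage_sites=detect_cleavage_sites(profile, structure, min_drop_fraction),
    )


def per_base_table(
    profile: CoverageProfile,
    structure: SecondaryStructure,
    sequence: str,
    min_drop_fraction: float = 0.5,
) -> pd.DataFrame:
    """Annotated per-base table: position, base, pairing, normalized coverage, cleavage.

    Sufficient to regenerate structure-colored renderings externally.
    """
    cov = structure_coverage(profile, structure, min_drop_fraction)
    cleave = {s.position for s in cov.cleavage_sites}
    return pd.DataFrame(
        {
            "position": np.arange(1, profile.length + 1),
            "base": list(sequence),
            "paired": [structure.is_paired(p) for p in range(1, profile.length + 1)],
            "normalized_coverage": cov.normalized,
            "cleavage_site": [p in cleave for p in range(1, profile.length + 1)],
        }
    )
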