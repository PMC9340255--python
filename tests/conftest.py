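"""Shared fixtures: the bundled synthetic reference set, toy references and
an exhaustive brute-force alignment oracle used to verify the seed-and-verify
aligner."""

from __future__ import annotations

import numpy as np
import pytest

from nmsrna import build_tiers, fixture_reference_set
from nmsrna.references import ReferenceRecord

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[int(b)] for b in rng.integers(0, 4, n))


def brute_force_alignments(read_seq: str, records, max_mismatch: int):
    """Exhaustive ungapped Hamming scan over every offset of every record.

    Returns sorted (ref_id, ref_start, mismatches) tuples with 1-based
    coordinates — the ground truth the seeded aligner must reproduce.
    """
    n = len(read_seq)
    hits = []
    for rec in records:
        for start0 in range(rec.length - n + 1):
            window = rec.sequence[start0 : start0 + n]
            mm = tuple(
                (start0 + i + 1, window[i], read_seq[i])
                for i in range(n)
                if window[i] != read_seq[i]
            )
            if len(mm) <= max_mismatch:
                hits.append((rec.id, start0 + 1, mm))
    return sorted(hits)


def alignment_tuples(alignments):
    return sorted(
        (
            a.ref_id,
            a.ref_start,
            tuple((m.ref_position, m.ref_base, m.read_base) for m in a.mismatches),
        )
        for a in alignments
    )


@pytest.fixture(scope="session")
def refset():
    return fixture_reference_set()


@pytest.fixture(scope="session")
def tiers(refset):
    return build_tiers(refset.records)


@pytest.fixture(scope="session")
def by_id(refset):
    return refset.by_id


@pytest.fixture(scope="session")
def toy_records():
    """30 random references, 60-200 nt, for oracle-equivalence tests."""
    rng = np.random.default_rng(7)
    return [
        ReferenceRecord(
            id=f"toy{i:02d}",
            rna_class="lncRNA",
            subclass="",
            sequence=random_seq(rng, int(rng.integers(60, 201))),
        )
        for i in range(30)
    ]
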