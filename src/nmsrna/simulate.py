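"""TGIRT-style small-RNA library simulator with per-read ground truth.

The restricted patient FASTQs are emulated by a generator whose defaults are
the study conditions: a ~43% miRNA / 57% nmsRNA mixture, class length peaks
(miRNA 22; tRF-5 33/27/19; tRF-3 37-38/22/18; tRF-1 20; rRF 39; mt-rRF 37;
YRF 33/35/31; snoRF 35/28), anchored fragment sampling (5' tRFs start at
position 1, 3' tRFs end at the CCA end, rRFs start at discrete hotspots, YRFs
on either side of a fixed cleavage position in the preterminal loop),
misincorporation injected at canonical modification sites, up to two
non-templated 3' additions on miRNAs, a uniform per-base sequencing error,
and a ligated 3' adapter.  Every read has exactly one truth record; output is
byte-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments import DEFAULT_BOUNDARIES, TRF_SERIES, TrfBoundaries
from .fixtures import DEFAULT_YRF_CLEAVAGE
from .preprocess import NEB_3P_ADAPTER, NEB_5P_ADAPTER
from .references import ReferenceRecord

_BASES = "ACGT"


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModificationSiteSpec:
    """One misincorporation site: where it sits, how often and into what it reads.

    ``selector`` narrows the references carrying the site: for tRNA-class
    sites a subclass prefix (``"Glu"``; empty selects every tRNA), for rRNA
    sites the molecule subclass (``"28S"``).  ``offset`` follows the canonical
    site convention: 1-based from the 5' end for ``five_prime``/``absolute``,
    bases upstream of the 3' terminal base for ``three_prime``.
    """

    label: str
    classes: frozenset[str]
    selector: str
    anchoring: str
    offset: int
    rate: float
    spectrum: Mapping[str, float]  # read base -> probability, sums to 1

    def position_on(self, ref: ReferenceRecord) -> int:
        pos = ref.length - self.offset if self.anchoring == "three_prime" else self.offset
        if not 1 <= pos <= ref.length:
            raise SimulationConfigError(
                f"site {self.label} resolves outside {ref.id} (length {ref.length})"
            )
        return pos


DEFAULT_MOD_SITES: tuple[ModificationSiteSpec, ...] = (
    ModificationSiteSpec(
        "tRNA:9", frozenset({"tRNA"}), "Glu", "five_prime", 9, 0.40,
        {"T": 0.5, "A": 0.3, "C": 0.2},
    ),
    ModificationSiteSpec(
        "tRNA:9", frozenset({"tRNA"}), "Asp", "five_prime", 9, 0.25,
        {"T": 0.6, "G": 0.3, "C": 0.1},
    ),
    ModificationSiteSpec(
        "tRNA:26", frozenset({"tRNA"}), "Leu", "five_prime", 26, 0.35,
        {"T": 0.5, "A": 0.3, "C": 0.2},
    ),
    ModificationSiteSpec(
        "tRNA:58", frozenset({"tRNA", "mt_tRNA"}), "", "three_prime", 18, 0.45,
        {"T": 0.6, "G": 0.3, "C": 0.1},
    ),
    ModificationSiteSpec(
        "28S:1322", frozenset({"rRNA"}), "28S", "absolute", 1322, 0.60,
        {"T": 0.6, "G": 0.3, "C": 0.1},
    ),
    ModificationSiteSpec(
        "28S:4530", frozenset({"rRNA"}), "28S", "absolute", 4530, 0.50,
        {"C": 0.5, "G": 0.3, "A": 0.2},
    ),
    ModificationSiteSpec(
        "18S:1248", frozenset({"rRNA"}), "18S", "absolute", 1248, 0.40,
        {"C": 0.5, "G": 0.3, "A": 0.2},
    ),
)

# length models: length -> probability
DEFAULT_TRF_SUBTYPE_MIXTURE: dict[str, float] = {
    "tiR-5": 0.25,
    "tRF-5c": 0.12,
    "tRF-5a": 0.08,
    "tiR-3": 0.22,
    "tRF-3b": 0.12,
    "tRF-3a": 0.06,
    "tRF-1": 0.15,
}
DEFAULT_TRF_LENGTHS: dict[str, dict[int, float]] = {
    "tiR-5": {33: 0.6, 32: 0.2, 34: 0.2},
    "tRF-5c": {27: 1.0},
    "tRF-5a": {19: 1.0},
    "tiR-3": {37: 0.7, 38: 0.3},
    "tRF-3b": {22: 1.0},
    "tRF-3a": {18: 1.0},
    "tRF-1": {20: 0.8, 19: 0.1, 21: 0.1},
}
DEFAULT_RRF_LENGTHS = {39: 0.8, 38: 0.1, 40: 0.1}
DEFAULT_MT_RRF_LENGTHS = {37: 0.8, 36: 0.1, 38: 0.1}
DEFAULT_SNORF_LENGTHS = {35: 0.6, 28: 0.4}

# rRF starts concentrate at discrete hotspot regions; defaults put the
# canonical sites inside the dominant windows
DEFAULT_RRF_HOTSPOTS: tuple[tuple[str, int, float], ...] = (
    ("28S_syn", 1303, 0.30),
    ("28S_syn", 4511, 0.30),
    ("18S_syn", 1229, 0.20),
    ("mt16S_syn", 500, 0.20),
)

DEFAULT_YRF_WEIGHTS = {"RNY5_syn": 0.5, "RNY4_syn": 0.3, "RNY1_syn": 0.2}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; defaults are the study conditions."""

    seed: int = 0
    n_reads: int = 100_000
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "miRNA": 0.43,
            "tRF": 0.20,
            "rRF": 0.25,
            "YRF": 0.05,
            "other": 0.07,
        }
    )
    trf_subtype_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRF_SUBTYPE_MIXTURE)
    )
    trf_lengths: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRF_LENGTHS.items()}
    )
    rrf_lengths: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_RRF_LENGTHS))
    mt_rrf_lengths: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MT_RRF_LENGTHS)
    )
    snorf_lengths: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SNORF_LENGTHS)
    )
    rrf_hotspots: Sequence[tuple[str, int, float]] = DEFAULT_RRF_HOTSPOTS
    rrf_start_jitter: int = 2
    yrf_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_YRF_WEIGHTS))
    yrf_cleavage: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_YRF_CLEAVAGE))
    yrf_five_prime_fraction: float = 0.15
    yrf_end_jitter: int = 1
    trf_end_jitter_prob: float = 0.1  # chance of a 1-nt ragged anchored end (tRF and YRF)
    modification_sites: Sequence[ModificationSiteSpec] = DEFAULT_MOD_SITES
    nt_addition_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    sequencing_error_rate: float = 0.001
    adapter_3p: str = NEB_3P_ADAPTER
    adapter_5p: str = NEB_5P_ADAPTER
    p_adapter_dimer: float = 0.002
    p_short_insert: float = 0.003
    boundaries: TrfBoundaries = DEFAULT_BOUNDARIES

    def validate(self) -> None:
        problems = []
        if self.n_reads < 0:
            problems.append("n_reads must be >= 0")
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-9:
            problems.append("class_mixture fractions must sum to 1")
        if abs(sum(self.trf_subtype_mixture.values()) - 1.0) > 1e-9:
            problems.append("trf_subtype_mixture must sum to 1")
        for rates in (
            [self.sequencing_error_rate, self.p_adapter_dimer, self.p_short_insert,
             self.yrf_five_prime_fraction]
            + [s.rate for s in self.modification_sites]
        ):
            if not 0.0 <= rates <= 1.0:
                problems.append(f"rate {rates} outside [0, 1]")
        if abs(sum(self.nt_addition_probs) - 1.0) > 1e-9:
            problems.append("nt_addition_probs must sum to 1")
        for spec in self.modification_sites:
            if abs(sum(spec.spectrum.values()) - 1.0) > 1e-9:
                problems.append(f"spectrum of {spec.label} must sum to 1")
        if problems:
            raise SimulationConfigError("; ".join(problems))


@dataclass
class TruthRecord:
    """Ground truth for one synthetic read."""

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    rna_class: str
    subtype: str
    injected: str  # "pos:REF>ALT;..." in reference coordinates
    added_3p: str
    seq_errors: str  # "readpos:REF>ALT;..." in read coordinates (insert only)
    insert_length: int


def _draw(rng: np.random.Generator, model: Mapping, n: int = 1) -> list:
    keys = list(model.keys())
    probs = np.array([model[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    return [keys[i] for i in idx]


def _truth_subtype(start: int, end: int, ref: ReferenceRecord, boundaries: TrfBoundaries) -> str:
    from .fragments import classify_trf
    from .mapper import Alignment

    stub = Alignment(read_id="", ref_id=ref.id, ref_start=start, ref_end=end)
    return classify_trf(stub, ref, boundaries=boundaries)


def sample_fragment(
    ref: ReferenceRecord,
    rule: str,
    length: int,
    rng: np.random.Generator,
    cleavage: int | None = None,
    hotspot_start: int | None = None,
    jitter: int = 0,
) -> tuple[int, int]:
    """Sample 1-based (start, end) fragment coordinates under a class rule.

    Rules: ``five_prime`` (starts at position 1), ``three_prime`` (ends at the
    reference 3' end / CCA), ``windowed`` (starts near ``hotspot_start``),
    ``cleavage_5p`` / ``cleavage_3p`` (ends at / starts after ``cleavage``).
    ``jitter`` allows a ragged +-jitter shift of the anchored coordinate.
    """
    L = ref.length
    if length > L:
        raise SimulationConfigError(
            f"fragment length {length} exceeds reference {ref.id} (length {L})"
        )
    j = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
    if rule == "five_prime":
        start = max(1, 1 + j)
        end = start + length - 1
    elif rule == "three_prime":
        end = min(L, L + j)
        start = end - length + 1
    elif rule == "windowed":
        assert hotspot_start is not None
        start = min(max(1, hotspot_start + j), L - length + 1)
        end = start + length - 1
    elif rule == "cleavage_5p":
        # everything 5' of the cleavage position (ragged by j); length unused
        assert cleavage is not None
        start = 1
        end = min(L, max(1, cleavage + j))
    elif rule == "cleavage_3p":
        # everything 3' of the cleavage position (ragged by j); length unused
        assert cleavage is not None
        start = max(1, min(L, cleavage + 1 + j))
        end = L
    elif rule == "uniform":
        start = int(rng.integers(1, L - length + 2))
        end = start + length - 1
    else:
        raise SimulationConfigError(f"unknown fragment rule {rule!r}")
    if start < 1 or end > L or end < start:
        raise SimulationConfigError(f"fragment {start}-{end} out of bounds on {ref.id}")
    return start, end


def resolve_sites(
    sites: Sequence[ModificationSiteSpec], records: Sequence[ReferenceRecord]
) -> dict[str, list[tuple[int, ModificationSiteSpec]]]:
    """Map each reference id to its (position, spec) misincorporation sites."""
    out: dict[str, list[tuple[int, ModificationSiteSpec]]] = {}
    for spec in sites:
        for rec in records:
            if rec.rna_class not in spec.classes:
                continue
            if spec.selector and not rec.subclass.startswith(spec.selector):
                continue
            try:
                pos = spec.position_on(rec)
            except SimulationConfigError:
                continue
            out.setdefault(rec.id, []).append((pos, spec))
    return out


def inject_misincorporation(
    fragment: str,
    ref_start: int,
    sites: Sequence[tuple[int, ModificationSiteSpec]],
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Mutate each covered site independently with its rate; returns truth entries.

    Truth entries are (reference position, from base, to base).
    """
    chars = list(fragment)
    events = []
    for pos, spec in sites:
        i = pos - ref_start  # 0-based within fragment
        if not 0 <= i < len(chars):
            continue
        if rng.random() >= spec.rate:
            continue
        frm = chars[i]
        choices = [(b, p) for b, p in spec.spectrum.items() if b != frm]
        if not choices:
            continue
        probs = np.array([p for _, p in choices])
        to = choices[int(rng.choice(len(choices), p=probs / probs.sum()))][0]
        chars[i] = to
        events.append((pos, frm, to))
    return "".join(chars), events


def _apply_seq_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str]]]:
    if rate <= 0:
        return seq, []
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq, []
    chars = list(seq)
    events = []
    for i in hits:
        frm = chars[i]
        alternatives = [b for b in _BASES if b != frm]
        to = alternatives[int(rng.integers(0, 3))]
        chars[i] = to
        events.append((int(i) + 1, frm, to))
    return "".join(chars), events


def simulate_library(
    config: SimulationConfig,
    records: Sequence[ReferenceRecord],
    out_fastq: str | Path,
    out_truth: str | Path | None = None,
) -> pd.DataFrame:
    """Write a FASTQ (+ truth TSV) and return the truth table.

    Reads are insert + 3' adapter with uniform qualities; adapter-dimer and
    short-insert artifact reads (for exercising the preprocessing filters)
    carry class ``artifact`` and an empty ref_id in the truth table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    by_class: dict[str, list[ReferenceRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.rna_class, []).append(rec)
    site_map = resolve_sites(config.modification_sites, records)
    hotspots = list(config.rrf_hotspots)
    hs_probs = np.array([w for _, _, w in hotspots])
    hs_probs = hs_probs / hs_probs.sum() if len(hotspots) else hs_probs
    by_id = {r.id: r for r in records}
    yrf_ids = list(config.yrf_weights)
    yrf_probs = np.array([config.yrf_weights[y] for y in yrf_ids], dtype=float)
    if len(yrf_probs):
        yrf_probs = yrf_probs / yrf_probs.sum()

    mix_keys = list(config.class_mixture)
    mix_probs = np.array([config.class_mixture[k] for k in mix_keys], dtype=float)
    classes = rng.choice(len(mix_keys), size=config.n_reads, p=mix_probs)
    artifact_draws = rng.random(config.n_reads)

    truth_rows: list[TruthRecord] = []
    fastq_lines: list[str] = []

    def emit(read_id: str, insert: str, truth: TruthRecord) -> None:
        seq = insert + config.adapter_3p
        fastq_lines.append(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
        truth_rows.append(truth)

    for i, ci in enumerate(classes):
        rid = f"read{i:07d}"
        # artifact reads replace the drawn class with probability p_dimer+p_short
        a = artifact_draws[i]
        if a < config.p_adapter_dimer:
            # trimmed remnant is pure 5' adapter sequence
            emit(
                rid,
                config.adapter_5p,
                TruthRecord(rid, "", 0, 0, "artifact", "adapter_dimer", "", "", "", 0),
            )
            continue
        if a < config.p_adapter_dimer + config.p_short_insert:
            n = int(rng.integers(8, 14))
            insert = "".join(_BASES[int(b)] for b in rng.integers(0, 4, n))
            emit(rid, insert, TruthRecord(rid, "", 0, 0, "artifact", "short_insert", "", "", "", n))
            continue

        cls = mix_keys[ci]
        if cls == "miRNA":
            ref = by_class["miRNA"][int(rng.integers(0, len(by_class["miRNA"])))]
            start, end = 1, ref.length
            rule_subtype = "miRNA"
        elif cls == "tRF":
            subtype = _draw(rng, config.trf_subtype_mixture)[0]
            length = int(_draw(rng, config.trf_lengths[subtype])[0])
            jit = 1 if rng.random() < config.trf_end_jitter_prob else 0
            if subtype == "tRF-1":
                pool = by_class["tRNA_trailer"]
                ref = pool[int(rng.integers(0, len(pool)))]
                start, end = 1, min(length, ref.length)
            else:
                pool = by_class["tRNA"]
                ref = pool[int(rng.integers(0, len(pool)))]
                rule = "five_prime" if TRF_SERIES[subtype] == "5p" else "three_prime"
                start, end = sample_fragment(ref, rule, length, rng, jitter=jit)
            rule_subtype = _truth_subtype(start, end, ref, config.boundaries)
        elif cls == "rRF":
            hi = int(rng.choice(len(hotspots), p=hs_probs))
            ref_id, hstart, _w = hotspots[hi]
            ref = by_id[ref_id]
            model = config.mt_rrf_lengths if ref.rna_class == "mt_rRNA" else config.rrf_lengths
            length = int(_draw(rng, model)[0])
            start, end = sample_fragment(
                ref, "windowed", length, rng, hotspot_start=hstart, jitter=config.rrf_start_jitter
            )
            rule_subtype = "rRF" if ref.rna_class == "rRNA" else "mt-rRF"
        elif cls == "YRF":
            yid = yrf_ids[int(rng.choice(len(yrf_ids), p=yrf_probs))]
            ref = by_id[yid]
            c = config.yrf_cleavage[yid]
            jit = config.yrf_end_jitter if rng.random() < config.trf_end_jitter_prob else 0
            if rng.random() < config.yrf_five_prime_fraction:
                start, end = sample_fragment(
                    ref, "cleavage_5p", c, rng, cleavage=c, jitter=jit
                )
                rule_subtype = "YRF-5p"
            else:
                start, end = sample_fragment(
                    ref, "cleavage_3p", ref.length - c, rng, cleavage=c, jitter=jit
                )
                rule_subtype = "YRF-3p"
        else:  # "other": snoRNA-derived fragments at random windows
            pool = by_class["snoRNA"]
            ref = pool[int(rng.integers(0, len(pool)))]
            length = int(_draw(rng, config.snorf_lengths)[0])
            start, end = sample_fragment(ref, "uniform", length, rng)
            rule_subtype = "snoRF"

        insert = ref.sequence[start - 1 : end]
        insert, injected = inject_misincorporation(
            insert, start, site_map.get(ref.id, ()), rng
        )
        added = ""
        if cls == "miRNA":
            n_add = int(rng.choice(3, p=np.array(config.nt_addition_probs)))
            added = "".join(_BASES[int(b)] for b in rng.integers(0, 4, n_add))
        insert_mut, errors = _apply_seq_errors(insert, config.sequencing_error_rate, rng)
        emit(
            rid,
            insert_mut + added,
            TruthRecord(
                read_id=rid,
                ref_id=ref.id,
                ref_start=start,
                ref_end=end,
                rna_class=ref.rna_class,
                subtype=rule_subtype,
                injected=";".join(f"{p}:{f}>{t}" for p, f, t in injected),
                added_3p=added,
                seq_errors=";".join(f"{p}:{f}>{t}" for p, f, t in errors),
                insert_length=end - start + 1 + len(added),
            ),
        )

    Path(out_fastq).write_text("".join(fastq_lines))
    truth = pd.DataFrame([t.__dict__ for t in truth_rows])
    if truth.empty:
        truth = pd.DataFrame(
            columns=[
                "read_id", "ref_id", "ref_start", "ref_end", "rna_class", "subtype",
                "injected", "added_3p", "seq_errors", "insert_length",
            ]
        )
    if out_truth is not None:
        truth.to_csv(out_truth, sep="\t", index=False)
    return truth
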