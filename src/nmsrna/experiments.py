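"""Simulation-based validation experiments.

Because the patient libraries behind the published analysis are
access-restricted, the pipeline's correctness is demonstrated on synthetic
libraries with known truth: class-mixture recovery, modification-rate
recovery at the canonical sites, tRF subtype accuracy, length-mode recovery,
mismatch-type asymmetry and YRF cleavage recovery.  These experiments are
shared by the test suite and the reproduction script.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotate import AnnotatedRead, annotate_library, class_fraction_summary
from .fixtures import fixture_reference_set
from .fragments import classify_trf, modal_lengths, size_histograms
from .modcall import (
    CANONICAL_SITES,
    aggregate_trf_profiles,
    mismatch_type_fractions,
    profiles_from_annotated,
    site_report,
)
from .preprocess import PreprocessStats, filter_reads, read_fastq
from .references import ReferenceRecord, ReferenceTier, build_tiers
from .simulate import ModificationSiteSpec, SimulationConfig, simulate_library
from .ystructure import detect_cleavage_sites

# the classes the per-class summary groups into (tRF = tRNA-derived incl.
# trailer and mitochondrial; rRF = genomic + mitochondrial rRNA-derived)
CLASS_GROUPS: dict[str, tuple[str, ...]] = {
    "miRNA": ("miRNA",),
    "tRF": ("tRNA", "mt_tRNA", "tRNA_trailer"),
    "rRF": ("rRNA", "mt_rRNA"),
    "YRF": ("YRNA",),
    "other": ("snoRNA", "snRNA", "lncRNA", "mRNA"),
}


@dataclass
class LibraryRun:
    """A simulated library pushed through preprocess + annotation."""

    config: SimulationConfig
    records: list[ReferenceRecord]
    by_id: dict[str, ReferenceRecord]
    tiers: list[ReferenceTier]
    truth: pd.DataFrame
    stats: PreprocessStats
    annotated: list[AnnotatedRead]
    unmapped: int
    structures: dict = field(default_factory=dict)


def run_simulated_library(
    config: SimulationConfig,
    records: Sequence[ReferenceRecord] | None = None,
    structures: Mapping | None = None,
) -> LibraryRun:
    """Simulate one library and run it through preprocessing and annotation."""
    if records is None:
        refset = fixture_reference_set()
        records, structures = refset.records, refset.structures
    records = list(records)
    tiers = build_tiers(records)
    with tempfile.TemporaryDirectory() as td:
        fq = Path(td) / "sim.fastq"
        truth = simulate_library(config, records, fq)
        reads, stats = filter_reads(
            read_fastq(fq),
            three_prime_adapter=config.adapter_3p,
            five_prime_adapter=config.adapter_5p,
        )
    annotated, unmapped = annotate_library(reads, tiers)
    return LibraryRun(
        config=config,
        records=records,
        by_id={r.id: r for r in records},
        tiers=tiers,
        truth=truth,
        stats=stats,
        annotated=annotated,
        unmapped=unmapped,
        structures=dict(structures or {}),
    )


def grouped_class_fractions(run: LibraryRun) -> dict[str, float]:
    """Per-group percentage of mapped reads (miRNA / tRF / rRF / YRF / other)."""
    per_class = class_fraction_summary(run.annotated, run.by_id)
    return {
        group: sum(per_class.get(c, 0.0) for c in classes)
        for group, classes in CLASS_GROUPS.items()
    }


def truth_class_fractions(run: LibraryRun) -> dict[str, float]:
    """The realized simulated mixture (non-artifact reads), in percent."""
    real = run.truth[run.truth.rna_class != "artifact"]
    per_class = real.rna_class.value_counts(normalize=True) * 100.0
    return {
        group: float(sum(per_class.get(c, 0.0) for c in classes))
        for group, classes in CLASS_GROUPS.items()
    }


# ---------------------------------------------------------------------------
# modification-rate recovery


def _calibration_records() -> tuple[list[ReferenceRecord], None]:
    """One tRNA per site-bearing amino-acid group plus the rRNA surrogates,
    so every canonical site accumulates deep coverage quickly."""
    refset = fixture_reference_set()
    keep_tr = {"tRNA-Glu-TTC-syn1", "tRNA-Leu-AAG-syn1", "tRNA-Arg-TCT-syn1"}
    keep_rr = {"28S_syn", "18S_syn"}
    records = [r for r in refset.records if r.id in keep_tr | keep_rr]
    return records, None


def _calibration_config(seed: int, rate: float, n_reads: int) -> SimulationConfig:
    spectrum_g = {"T": 0.5, "A": 0.3, "C": 0.2}
    spectrum_a = {"T": 0.6, "G": 0.3, "C": 0.1}
    spectrum_t = {"C": 0.5, "G": 0.3, "A": 0.2}
    sites = (
        ModificationSiteSpec("tRNA:9", frozenset({"tRNA"}), "Glu", "five_prime", 9, rate, spectrum_g),
        ModificationSiteSpec("tRNA:26", frozenset({"tRNA"}), "Leu", "five_prime", 26, rate, spectrum_g),
        ModificationSiteSpec("tRNA:58", frozenset({"tRNA"}), "Arg", "three_prime", 18, rate, spectrum_a),
        ModificationSiteSpec("28S:1322", frozenset({"rRNA"}), "28S", "absolute", 1322, rate, spectrum_a),
        ModificationSiteSpec("28S:4530", frozenset({"rRNA"}), "28S", "absolute", 4530, rate, spectrum_t),
        ModificationSiteSpec("18S:1248", frozenset({"rRNA"}), "18S", "absolute", 1248, rate, spectrum_t),
    )
    return SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        class_mixture={"tRF": 0.5, "rRF": 0.5},
        trf_subtype_mixture={
            "tiR-5": 0.30, "tRF-5c": 0.15, "tRF-5a": 0.05,
            "tiR-3": 0.30, "tRF-3b": 0.15, "tRF-3a": 0.05,
        },
        rrf_hotspots=(("28S_syn", 1303, 0.4), ("28S_syn", 4511, 0.4), ("18S_syn", 1229, 0.2)),
        modification_sites=sites,
    )


SITE_GROUPS = {
    "tRNA:9": "Glu",
    "tRNA:26": "Leu",
    "tRNA:58": "Arg",
    "28S:1322": "28S",
    "28S:4530": "28S",
    "18S:1248": "18S",
}

# where each calibration site lives in reference coordinates
_SITE_REF_POSITIONS = {
    "tRNA:9": ("tRNA-Glu-TTC-syn1", 9),
    "tRNA:26": ("tRNA-Leu-AAG-syn1", 26),
    "tRNA:58": ("tRNA-Arg-TCT-syn1", 58),  # 76 nt - 18
    "28S:1322": ("28S_syn", 1322),
    "28S:4530": ("28S_syn", 4530),
    "18S:1248": ("18S_syn", 1248),
}


def realized_injection_pct(truth: pd.DataFrame, ref_id: str, position: int) -> tuple[float, int]:
    """Bookkept injection fraction among truth reads covering a site."""
    cov = truth[
        (truth.ref_id == ref_id)
        & (truth.ref_start <= position)
        & (truth.ref_end >= position)
    ]
    if cov.empty:
        return 0.0, 0
    def _hit(events: str) -> bool:
        return any(
            int(e.split(":")[0]) == position for e in str(events).split(";") if e
        )
    return 100.0 * cov.injected.map(_hit).mean(), len(cov)


def canonical_site_table(run: LibraryRun, min_coverage: float = 10.0) -> pd.DataFrame:
    """Site report (one synthetic sample) for a library run."""
    trna = profiles_from_annotated(
        run.annotated, run.by_id, classes=frozenset({"tRNA", "mt_tRNA"})
    )
    kinds = {
        "tRNA_five_prime": aggregate_trf_profiles(trna, run.by_id, anchor="five_prime"),
        "tRNA_three_prime": aggregate_trf_profiles(trna, run.by_id, anchor="three_prime"),
        "rRNA": {
            run.by_id[rid].subclass: prof
            for rid, prof in profiles_from_annotated(
                run.annotated, run.by_id, classes=frozenset({"rRNA", "mt_rRNA"})
            ).items()
        },
    }
    return site_report({"sim": kinds}, CANONICAL_SITES, min_coverage=min_coverage)


def modification_rate_recovery(
    seed: int, rate_pct: float, n_reads: int = 30_000
) -> pd.DataFrame:
    """Inject one rate at all six canonical sites; return recovery per site.

    ``realized_pct`` is the bookkept injection fraction among truth reads
    covering the site (the injection process is itself binomial, so the
    realized fraction — not the nominal rate — is the recovery oracle).
    Columns: site, group, injected_pct, realized_pct, recovered_pct, depth.
    """
    records, _ = _calibration_records()
    run = run_simulated_library(
        _calibration_config(seed, rate_pct / 100.0, n_reads), records=records
    )
    table = canonical_site_table(run)
    rows = []
    for site, group in SITE_GROUPS.items():
        sel = table[(table.site == site) & (table.group == group)]
        row = sel.iloc[0]
        ref_id, pos = _SITE_REF_POSITIONS[site]
        realized, _n_truth = realized_injection_pct(run.truth, ref_id, pos)
        rows.append((site, group, rate_pct, realized, row.mismatch_index, row.depth))
    return pd.DataFrame(
        rows,
        columns=["site", "group", "injected_pct", "realized_pct", "recovered_pct", "depth"],
    )


# ---------------------------------------------------------------------------
# tRF subtype accuracy


def subtype_accuracy(seed: int, n_reads: int = 10_000) -> tuple[float, int]:
    """Fraction of simulated tRF reads whose recovered subtype matches truth.

    Modification injection is disabled (geometry, not mismatch chemistry, is
    under test); each read's classification is taken from its alignment on the
    truth reference.
    """
    config = SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        class_mixture={"tRF": 1.0},
        modification_sites=(),
        p_adapter_dimer=0.0,
        p_short_insert=0.0,
    )
    run = run_simulated_library(config)
    truth_by_read = run.truth.set_index("read_id")
    total = correct = 0
    for ann in run.annotated:
        row = truth_by_read.loc[ann.read_id]
        aln = next((a for a in ann.alignments if a.ref_id == row.ref_id), None)
        if aln is None:
            total += 1
            continue
        total += 1
        correct += classify_trf(aln, run.by_id[aln.ref_id]) == row.subtype
    return (100.0 * correct / total if total else 0.0), total


# ---------------------------------------------------------------------------
# length modes


def length_mode_report(run: LibraryRun) -> tuple[dict[str, int], dict[str, int], pd.Series]:
    """(per-class modes, per-tRF-subtype modes, YRF length histogram)."""
    hists = size_histograms(run.annotated, run.by_id)
    class_modes = modal_lengths(hists)
    subtype_modes = modal_lengths(hists, by_subtype=True)
    yrf = (
        hists[hists.rna_class == "YRNA"].groupby("length")["rpm"].sum().sort_index()
    )
    return class_modes, subtype_modes, yrf


# ---------------------------------------------------------------------------
# mismatch-type asymmetry


def mismatch_asymmetry(seed: int, n_reads: int = 20_000) -> pd.DataFrame:
    """Plant G-type misincorporation on 5' tRFs only and A-type on 3' tRFs
    only; return the per-series mismatch-type fractions."""
    spectrum_g = {"T": 0.5, "A": 0.3, "C": 0.2}
    spectrum_a = {"T": 0.6, "G": 0.3, "C": 0.1}
    g9_subclasses = ("Glu", "Gly", "Leu", "Arg", "Ser")  # G at position 9
    sites = tuple(
        ModificationSiteSpec("tRNA:9", frozenset({"tRNA"}), sub, "five_prime", 9, 0.30, spectrum_g)
        for sub in g9_subclasses
    ) + (
        ModificationSiteSpec("tRNA:58", frozenset({"tRNA"}), "", "three_prime", 18, 0.30, spectrum_a),
    )
    config = SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        class_mixture={"tRF": 1.0},
        trf_subtype_mixture={
            "tiR-5": 0.35, "tRF-5c": 0.10, "tRF-5a": 0.05,
            "tiR-3": 0.35, "tRF-3b": 0.10, "tRF-3a": 0.05,
        },
        modification_sites=sites,
    )
    run = run_simulated_library(config)
    return mismatch_type_fractions(run.annotated, run.by_id)


# ---------------------------------------------------------------------------
# YRF cleavage


def cleavage_recovery(run: LibraryRun) -> dict[str, dict]:
    """Detected cleavage site vs simulated truth per covered YRNA."""
    profiles = profiles_from_annotated(run.annotated, run.by_id, classes=frozenset({"YRNA"}))
    out = {}
    for yid, prof in profiles.items():
        struct = run.structures.get(yid)
        if struct is None:
            continue
        sites = detect_cleavage_sites(prof, struct, min_drop_fraction=0.5)
        truth_pos = run.config.yrf_cleavage.get(yid)
        out[yid] = {
            "truth": truth_pos,
            "detected": sites[0].position if sites else None,
            "region": sites[0].region if sites else None,
        }
    return out
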