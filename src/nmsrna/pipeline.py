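"""Pipeline orchestration: preprocess -> annotate -> fragments -> modcall -> ystructure.

One sample flows FASTQ -> trimmed/filtered reads -> tiered annotation ->
count/RPM tables, length histograms, tRF subtype tables, canonical-site
mismatch report, mismatch-type fractions and YRNA structure coverage; all
outputs are TSV/JSON files plus an in-memory :class:`LibrarySummary`.  Reruns
with identical inputs and configuration are deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    AnnotatedRead,
    annotate_library,
    class_fraction_summary,
    compute_rpm,
    count_table,
)
from .fixtures import FixtureReferenceSet, fixture_reference_set
from .fragments import (
    modal_lengths,
    sequence_rpm_table,
    size_histograms,
)
from .modcall import (
    CANONICAL_SITES,
    aggregate_trf_profiles,
    mismatch_type_fractions,
    profiles_from_annotated,
    site_report,
)
from .preprocess import (
    DEFAULT_MAX_ERROR_RATE,
    DEFAULT_MIN_LENGTH,
    DEFAULT_MIN_OVERLAP,
    DEFAULT_MIN_OVERLAP_5P,
    NEB_3P_ADAPTER,
    NEB_5P_ADAPTER,
    PreprocessStats,
    filter_reads,
    read_fastq,
)
from .references import ReferenceRecord, ReferenceTier, build_tiers
from .ystructure import CleavageSite, SecondaryStructure, detect_cleavage_sites, per_base_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """All tunable pipeline parameters with their declared defaults."""

    min_length: int = DEFAULT_MIN_LENGTH
    adapter_3p: str = NEB_3P_ADAPTER
    adapter_5p: str = NEB_5P_ADAPTER
    min_overlap: int = DEFAULT_MIN_OVERLAP
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE
    min_overlap_5p: int = DEFAULT_MIN_OVERLAP_5P
    max_mismatch: int = 1
    max_internal_mismatch: int = 1
    max_nt_addition: int = 2
    seed_length: int = 7
    tol5: int = 1
    tol3: int = 1
    site_min_coverage: float = 10.0
    min_drop_fraction: float = 0.5


@dataclass
class LibrarySummary:
    """Per-sample results: accounting, class fractions, site calls, cleavage."""

    sample_id: str
    stats: PreprocessStats
    mapped_reads: int
    unmapped_reads: int
    class_fractions: dict[str, float]
    modal_lengths_by_class: dict[str, int]
    site_table: pd.DataFrame
    sequence_rpm: pd.DataFrame
    cleavage_sites: dict[str, list[CleavageSite]]
    top_sequences: pd.DataFrame


class PipelineConfigError(ValueError):
    pass


def run_sample(
    sample_id: str,
    fastq_path: str | Path,
    tiers: Sequence[ReferenceTier],
    records_by_id: dict[str, ReferenceRecord],
    structures: Mapping[str, SecondaryStructure],
    out_dir: str | Path,
    params: PipelineParams = PipelineParams(),
) -> LibrarySummary:
    """Run the full pipeline on one sample and write its output tables."""
    out = Path(out_dir) / sample_id
    out.mkdir(parents=True, exist_ok=True)

    reads, stats = filter_reads(
        read_fastq(fastq_path),
        min_length=params.min_length,
        five_prime_adapter=params.adapter_5p,
        three_prime_adapter=params.adapter_3p,
        min_overlap=params.min_overlap,
        max_error_rate=params.max_error_rate,
        min_overlap_5p=params.min_overlap_5p,
    )
    stats.to_json(out / "preprocess_stats.json")

    annotated, unmapped = annotate_library(
        reads,
        tiers,
        max_mismatch=params.max_mismatch,
        max_internal_mismatch=params.max_internal_mismatch,
        max_nt_addition=params.max_nt_addition,
    )
    if not annotated:
        raise PipelineConfigError(f"sample {sample_id}: no reads mapped")

    counts = compute_rpm(count_table(annotated, records_by_id))
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    fractions = class_fraction_summary(annotated, records_by_id)

    hists = size_histograms(
        annotated, records_by_id, tol5=params.tol5, tol3=params.tol3
    )
    hists.to_csv(out / "size_histograms.tsv", sep="\t", index=False)
    modes = modal_lengths(hists)

    mm_types = mismatch_type_fractions(
        annotated, records_by_id, tol5=params.tol5, tol3=params.tol3
    )
    mm_types.to_csv(out / "mismatch_type_fractions.tsv", sep="\t", index=False)

    # canonical-site mismatch report
    trna_profiles = profiles_from_annotated(
        annotated, records_by_id, classes=frozenset({"tRNA", "mt_tRNA"})
    )
    kinds = {
        "tRNA_five_prime": aggregate_trf_profiles(
            trna_profiles, records_by_id, anchor="five_prime"
        ),
        "tRNA_three_prime": aggregate_trf_profiles(
            trna_profiles, records_by_id, anchor="three_prime"
        ),
        "rRNA": {
            records_by_id[rid].subclass: prof
            for rid, prof in profiles_from_annotated(
                annotated, records_by_id, classes=frozenset({"rRNA", "mt_rRNA"})
            ).items()
        },
    }
    sites = site_report(
        {sample_id: kinds}, CANONICAL_SITES, min_coverage=params.site_min_coverage
    )
    sites.to_csv(out / "site_report.tsv", sep="\t", index=False)

    # YRNA structure coverage + cleavage
    cleavage: dict[str, list[CleavageSite]] = {}
    yrf_profiles = profiles_from_annotated(
        annotated, records_by_id, classes=frozenset({"YRNA"})
    )
    for rid, prof in yrf_profiles.items():
        struct = structures.get(rid)
        if struct is None:
            continue
        tbl = per_base_table(
            prof, struct, records_by_id[rid].sequence, params.min_drop_fraction
        )
        tbl.to_csv(out / f"ystructure_{rid}.tsv", sep="\t", index=False)
        cleavage[rid] = detect_cleavage_sites(prof, struct, params.min_drop_fraction)

    seq_rpm = sequence_rpm_table(annotated, records_by_id)
    seq_rpm.to_csv(out / "nmsrna_sequence_rpm.tsv", sep="\t", index=False)
    top = counts.sort_values("rpm", ascending=False).head(20)

    summary = LibrarySummary(
        sample_id=sample_id,
        stats=stats,
        mapped_reads=len(annotated),
        unmapped_reads=unmapped,
        class_fractions=fractions,
        modal_lengths_by_class=modes,
        site_table=sites,
        sequence_rpm=seq_rpm,
        cleavage_sites=cleavage,
        top_sequences=top,
    )
    (out / "summary.json").write_text(
        json.dumps(
            {
                "sample_id": sample_id,
                "nmsrna_version": __version__,
                "params": params.__dict__,
                "preprocess": stats.__dict__,
                "mapped_reads": len(annotated),
                "unmapped_reads": unmapped,
                "class_fractions_pct": fractions,
                "modal_lengths": modes,
            },
            indent=1,
            default=str,
        )
        + "\n"
    )
    return summary


@dataclass
class RunConfig:
    """Multi-sample run configuration (YAML-loadable)."""

    samples: dict[str, str]  # sample id -> FASTQ path
    out_dir: str
    reference_manifest: str | None = None  # None -> bundled synthetic set
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = PipelineParams(**raw.get("params", {}))
        return cls(
            samples=dict(raw["samples"]),
            out_dir=raw["out_dir"],
            reference_manifest=raw.get("reference_manifest"),
            params=params,
        )

    def validate(self) -> None:
        missing = [p for p in self.samples.values() if not Path(p).exists()]
        if missing:
            raise PipelineConfigError(f"missing sample FASTQs: {missing}")
        if self.reference_manifest and not Path(self.reference_manifest).exists():
            raise PipelineConfigError(
                f"missing reference manifest: {self.reference_manifest}"
            )


def load_references(
    config: RunConfig,
) -> tuple[list[ReferenceTier], dict[str, ReferenceRecord], dict[str, SecondaryStructure]]:
    if config.reference_manifest:
        from .references import load_reference_manifest

        tiers = load_reference_manifest(config.reference_manifest)
        records = [r for t in tiers for r in t.records]
        structures: dict[str, SecondaryStructure] = {}
    else:
        refset: FixtureReferenceSet = fixture_reference_set()
        records = refset.records
        structures = refset.structures
        tiers = build_tiers(records, seed_length=config.params.seed_length)
    return tiers, {r.id: r for r in records}, structures


def run_pipeline(config: RunConfig) -> dict[str, LibrarySummary]:
    """Run every sample; a failing sample is logged and skipped, others proceed."""
    config.validate()
    tiers, records_by_id, structures = load_references(config)
    summaries: dict[str, LibrarySummary] = {}
    for sample_id, fastq in config.samples.items():
        try:
            summaries[sample_id] = run_sample(
                sample_id,
                fastq,
                tiers,
                records_by_id,
                structures,
                config.out_dir,
                config.params,
            )
        except Exception:
            logger.exception("sample %s failed; continuing with remaining samples", sample_id)
    return summaries


def multi_sample_site_matrix(summaries: Mapping[str, LibrarySummary]) -> pd.DataFrame:
    """Rectangular (site, group) x sample matrix of mismatch indices.

    Null cells mean the coverage floor was not met in that sample.
    """
    if not summaries:
        raise ValueError("at least one sample summary required")
    frames = [s.site_table for s in summaries.values()]
    long = pd.concat(frames, ignore_index=True)
    # pivot keeps only observed (site, group) rows; cells stay NaN where the
    # per-sample coverage floor was unmet
    return long.pivot(index=["site", "group"], columns="sample", values="mismatch_index")
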