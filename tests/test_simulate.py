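"""Simulator contracts: determinism, truth bookkeeping, anchoring arithmetic,
injection and hotspot statistics."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from nmsrna.fixtures import fixture_reference_set
from nmsrna.simulate import (
    ModificationSiteSpec,
    SimulationConfig,
    SimulationConfigError,
    inject_misincorporation,
    resolve_sites,
    sample_fragment,
    simulate_library,
)


@pytest.fixture(scope="module")
def records():
    return fixture_reference_set().records


class TestSampleFragment:
    def test_five_prime_anchoring(self, by_id):
        rng = np.random.default_rng(0)
        ref = by_id["tRNA-Glu-TTC-syn1"]
        assert sample_fragment(ref, "five_prime", 33, rng) == (1, 33)

    def test_three_prime_anchoring_arithmetic(self, by_id):
        rng = np.random.default_rng(0)
        ref = by_id["tRNA-Glu-TTC-syn1"]  # 76 nt
        assert sample_fragment(ref, "three_prime", 18, rng) == (59, 76)

    def test_length_exceeding_reference_rejected(self, by_id):
        rng = np.random.default_rng(0)
        with pytest.raises(SimulationConfigError, match="exceeds"):
            sample_fragment(by_id["mir-syn-1"], "five_prime", 30, rng)

    def test_hotspot_start_distribution(self, by_id):
        """10k windowed draws from two hotspots match the configured weights
        (chi-square) and stay within the jitter window."""
        rng = np.random.default_rng(3)
        ref = by_id["28S_syn"]
        hotspots = [(1303, 0.7), (4511, 0.3)]
        counts = {1303: 0, 4511: 0}
        probs = np.array([w for _, w in hotspots])
        for _ in range(10_000):
            h = hotspots[int(rng.choice(2, p=probs))][0]
            start, end = sample_fragment(ref, "windowed", 39, rng, hotspot_start=h, jitter=2)
            assert abs(start - h) <= 2 and end - start + 1 == 39
            counts[h] += 1
        chi2 = sps.chisquare(
            [counts[1303], counts[4511]], f_exp=[10_000 * 0.7, 10_000 * 0.3]
        )
        assert chi2.pvalue > 1e-4


class TestInjection:
    def _site(self, rate, pos=9):
        return ModificationSiteSpec(
            "tRNA:9", frozenset({"tRNA"}), "Glu", "five_prime", pos, rate,
            {"T": 0.5, "A": 0.3, "C": 0.2},
        )

    def test_rate_one_always_mutates(self):
        rng = np.random.default_rng(1)
        frag, events = inject_misincorporation("G" * 20, 1, [(9, self._site(1.0))], rng)
        assert len(events) == 1 and frag[8] != "G"
        assert events[0][0] == 9 and events[0][1] == "G"

    def test_rate_zero_never_mutates(self):
        rng = np.random.default_rng(1)
        frag, events = inject_misincorporation("G" * 20, 1, [(9, self._site(0.0))], rng)
        assert events == [] and frag == "G" * 20

    def test_uncovered_site_skipped(self):
        rng = np.random.default_rng(1)
        frag, events = inject_misincorporation("G" * 10, 20, [(9, self._site(1.0))], rng)
        assert events == [] and frag == "G" * 10

    def test_binomial_rate_recovery(self):
        """Injected fraction over 10k fragments within 3 binomial SDs of 0.4."""
        rng = np.random.default_rng(5)
        n, hit = 10_000, 0
        site = [(9, self._site(0.4))]
        for _ in range(n):
            _, events = inject_misincorporation("G" * 20, 1, site, rng)
            hit += bool(events)
        sd = np.sqrt(0.4 * 0.6 / n)
        assert abs(hit / n - 0.4) <= 3 * sd

    def test_resolve_sites_selector_and_anchor(self, records):
        by = resolve_sites(
            [
                self._site(0.5),
                ModificationSiteSpec(
                    "tRNA:58", frozenset({"tRNA"}), "", "three_prime", 18, 0.5, {"T": 1.0}
                ),
            ],
            records,
        )
        glu = by["tRNA-Glu-TTC-syn1"]
        assert (9, ) in {(p,) for p, _ in glu}
        assert {p for p, s in glu if s.label == "tRNA:58"} == {58}
        assert all(
            s.label != "tRNA:9" for p, s in by.get("tRNA-Gly-GCC-syn1", []) if s.selector == "Glu"
        )


class TestSimulateLibrary:
    def test_zero_reads(self, records, tmp_path):
        cfg = SimulationConfig(seed=1, n_reads=0)
        truth = simulate_library(cfg, records, tmp_path / "x.fastq", tmp_path / "t.tsv")
        assert truth.empty and (tmp_path / "x.fastq").read_text() == ""

    def test_byte_determinism_under_seed(self, records, tmp_path):
        cfg = SimulationConfig(seed=42, n_reads=2000)
        t1 = simulate_library(cfg, records, tmp_path / "a.fastq", tmp_path / "a.tsv")
        t2 = simulate_library(cfg, records, tmp_path / "b.fastq", tmp_path / "b.tsv")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        t3 = simulate_library(
            SimulationConfig(seed=43, n_reads=2000), records, tmp_path / "c.fastq"
        )
        assert not t3.equals(t1)

    def test_truth_fastq_bijection_and_coordinates(self, records, tmp_path):
        cfg = SimulationConfig(seed=7, n_reads=3000)
        truth = simulate_library(cfg, records, tmp_path / "x.fastq")
        ids = [
            line[1:].strip()
            for line in (tmp_path / "x.fastq").read_text().splitlines()[::4]
        ]
        assert ids == truth.read_id.tolist()
        assert truth.read_id.is_unique
        by_id = {r.id: r for r in records}
        real = truth[truth.rna_class != "artifact"]
        for _, row in real.iterrows():
            ref = by_id[row.ref_id]
            assert 1 <= row.ref_start <= row.ref_end <= ref.length

    def test_inserts_match_truth_reconstruction(self, records, tmp_path):
        """Each read equals its source substring with the recorded injections,
        errors and additions applied, plus the 3' adapter."""
        cfg = SimulationConfig(seed=11, n_reads=1500)
        truth = simulate_library(cfg, records, tmp_path / "x.fastq")
        seqs = (tmp_path / "x.fastq").read_text().splitlines()[1::4]
        by_id = {r.id: r for r in records}
        checked = 0
        for seq, (_, row) in zip(seqs, truth.iterrows()):
            if row.rna_class == "artifact":
                continue
            insert = list(by_id[row.ref_id].sequence[row.ref_start - 1 : row.ref_end])
            for ev in filter(None, str(row.injected or "").split(";")):
                pos, sub = ev.split(":")
                insert[int(pos) - row.ref_start] = sub.split(">")[1]
            for ev in filter(None, str(row.seq_errors or "").split(";")):
                pos, sub = ev.split(":")
                insert[int(pos) - 1] = sub.split(">")[1]
            expect = "".join(insert) + str(row.added_3p or "") + cfg.adapter_3p
            assert seq == expect
            checked += 1
        assert checked > 1000

    def test_invalid_config_lists_violations(self, records, tmp_path):
        cfg = SimulationConfig(seed=1, n_reads=10, class_mixture={"miRNA": 0.9})
        with pytest.raises(SimulationConfigError, match="sum to 1"):
            simulate_library(cfg, records, tmp_path / "x.fastq")
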