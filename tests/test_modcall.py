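"""Coverage piling, mismatch index, amino-acid aggregation and site reports."""

from __future__ import annotations

import numpy as np
import pytest

from nmsrna.mapper import Alignment, Mismatch
from nmsrna.modcall import (
    CANONICAL_SITES,
    CoverageProfile,
    aggregate_trf_profiles,
    build_coverage,
    mismatch_index,
    mismatch_index_track,
    resolve_site_position,
    site_report,
)
from nmsrna.references import ReferenceRecord


def _aln(start, end, rid="ref", weight=1.0, mm=()):
    return Alignment(
        read_id="r", ref_id=rid, ref_start=start, ref_end=end,
        mismatches=tuple(mm), weight=weight,
    )


class TestBuildCoverage:
    def test_single_alignment_depth(self):
        prof = build_coverage([_aln(1, 20)], "ref", 50)
        assert prof.depth[:20].tolist() == [1.0] * 20
        assert prof.depth[20:].sum() == 0

    def test_fractional_weights_conserve_read_mass(self):
        halves = [_aln(1, 20, weight=0.5), _aln(11, 30, weight=0.5)]
        prof = build_coverage(halves, "ref", 50)
        assert prof.depth.sum() == pytest.approx(20.0)  # one read-length of mass

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            build_coverage([_aln(40, 60)], "ref", 50)

    def test_matches_naive_recount(self):
        """Vectorized pileup equals a per-position brute-force recount."""
        rng = np.random.default_rng(6)
        alns = []
        for _ in range(300):
            s = int(rng.integers(1, 80))
            e = s + int(rng.integers(14, 20))
            w = float(rng.choice([1.0, 0.5, 0.25]))
            mm = []
            if rng.random() < 0.3:
                p = int(rng.integers(s, e + 1))
                mm = [Mismatch(p, "A", "G")]
            alns.append(_aln(s, e, weight=w, mm=mm))
        prof = build_coverage(alns, "ref", 100)
        for p in range(1, 101):
            depth = sum(a.weight for a in alns if a.ref_start <= p <= a.ref_end)
            mass = sum(a.weight for a in alns for m in a.mismatches if m.ref_position == p)
            assert prof.depth[p - 1] == pytest.approx(depth)
            assert prof.mismatch_mass()[p - 1] == pytest.approx(mass)
        prof.check()


class TestMismatchIndex:
    def _profile(self):
        alns = [_aln(1, 20) for _ in range(7)] + [
            _aln(1, 20, mm=[Mismatch(10, "A", "G")]),
            _aln(1, 20, mm=[Mismatch(10, "A", "T")]),
            _aln(1, 20, mm=[Mismatch(10, "A", "C")]),
        ]
        return build_coverage(alns, "ref", 20)

    def test_direct_ratio(self):
        assert mismatch_index(self._profile(), 10) == pytest.approx(30.0)

    def test_zero_depth_is_null(self):
        prof = build_coverage([_aln(1, 10)], "ref", 20)
        assert mismatch_index(prof, 15) is None

    def test_coverage_floor(self):
        assert mismatch_index(self._profile(), 10, min_coverage=11) is None

    def test_out_of_range_position(self):
        with pytest.raises(ValueError, match="position"):
            mismatch_index(self._profile(), 21)

    def test_track_bounds_and_nan(self):
        track = mismatch_index_track(self._profile())
        assert np.nanmax(track) <= 100.0 and np.nanmin(track) >= 0.0
        empty = build_coverage([_aln(1, 10)], "ref", 20)
        assert np.isnan(mismatch_index_track(empty)[15])


class TestAggregation:
    def _records(self):
        return {
            "a": ReferenceRecord(id="a", rna_class="tRNA", subclass="Glu-TTC", sequence="A" * 72),
            "b": ReferenceRecord(id="b", rna_class="tRNA", subclass="Glu-CTC", sequence="A" * 76),
            "c": ReferenceRecord(id="c", rna_class="tRNA", subclass="Gly-GCC", sequence="A" * 76),
        }

    def test_identical_lengths_sum_elementwise(self):
        recs = self._records()
        profs = {
            "b": build_coverage([_aln(1, 30, "b")], "b", 76),
            "c": build_coverage([_aln(1, 30, "c")], "c", 76),
        }
        agg = aggregate_trf_profiles(profs, recs, grouping="amino_acid")
        assert set(agg) == {"Glu", "Gly"}
        assert agg["Glu"].depth[:30].tolist() == [1.0] * 30

    def test_three_prime_anchor_coaligns_terminal_bases(self):
        """Members of length 72 and 76 co-add at group position -1 (the CCA
        end) under the 3' anchor, and at position 1 under the 5' anchor."""
        recs = self._records()
        profs = {
            "a": build_coverage([_aln(53, 72, "a")], "a", 72),  # 3' 20-mer
            "b": build_coverage([_aln(57, 76, "b")], "b", 76),  # 3' 20-mer
        }
        agg3 = aggregate_trf_profiles(profs, recs, anchor="three_prime")["Glu"]
        assert agg3.length == 76
        assert agg3.depth[-1] == pytest.approx(2.0)
        assert agg3.depth[-20] == pytest.approx(2.0)
        assert agg3.depth[-21] == pytest.approx(0.0)
        agg5 = aggregate_trf_profiles(profs, recs, anchor="five_prime")["Glu"]
        assert agg5.depth[-1] == pytest.approx(1.0)  # only the 76-mer reaches 76

    def test_group_site_index_equals_hand_recount(self):
        """Mismatch index at the 3'-anchored position-58 site on a 2-member
        group equals the hand-aggregated pileup."""
        recs = self._records()
        # site at length-18: position 54 on the 72-mer, 58 on the 76-mer
        a_alns = [_aln(40, 72, "a", mm=[Mismatch(54, "A", "T")])] * 3 + [_aln(40, 72, "a")] * 2
        b_alns = [_aln(44, 76, "b", mm=[Mismatch(58, "A", "T")])] * 1 + [_aln(44, 76, "b")] * 4
        profs = {
            "a": build_coverage(a_alns, "a", 72),
            "b": build_coverage(b_alns, "b", 76),
        }
        agg = aggregate_trf_profiles(profs, recs, anchor="three_prime")["Glu"]
        site = next(s for s in CANONICAL_SITES if s.label == "tRNA:58")
        pos = resolve_site_position(site, agg.length)
        # hand recount: 10 covering reads, 4 mismatched
        assert agg.depth[pos - 1] == pytest.approx(10.0)
        assert mismatch_index(agg, pos, min_coverage=1) == pytest.approx(40.0)

    def test_mixed_class_rejected(self):
        recs = self._records()
        recs["r"] = ReferenceRecord(id="r", rna_class="rRNA", subclass="28S", sequence="A" * 100)
        profs = {"r": build_coverage([_aln(1, 20, "r")], "r", 100)}
        with pytest.raises(ValueError, match="tRNA-class"):
            aggregate_trf_profiles(profs, recs)

    def test_aggregation_linearity(self):
        """Total depth mass of the group equals the sum over members."""
        recs = self._records()
        rng = np.random.default_rng(12)
        profs = {}
        for rid in ("a", "b", "c"):
            L = recs[rid].length
            alns = []
            for _ in range(50):
                s = int(rng.integers(1, L - 15))
                alns.append(_aln(s, s + 14, rid, weight=float(rng.choice([1.0, 0.5]))))
            profs[rid] = build_coverage(alns, rid, L)
        for anchor in ("five_prime", "three_prime"):
            agg = aggregate_trf_profiles(profs, recs, anchor=anchor)
            total = sum(p.depth.sum() for p in agg.values())
            assert total == pytest.approx(sum(p.depth.sum() for p in profs.values()))


class TestSiteReport:
    def test_resolution_conventions(self):
        """5' sites resolve at their literal offset; the position-58 site
        resolves 18 bases upstream of the 3' terminal base."""
        t9 = next(s for s in CANONICAL_SITES if s.label == "tRNA:9")
        t58 = next(s for s in CANONICAL_SITES if s.label == "tRNA:58")
        assert resolve_site_position(t9, 76) == 9
        assert resolve_site_position(t58, 76) == 58
        assert resolve_site_position(t58, 72) == 54

    def test_report_nulls_and_values(self):
        glu = build_coverage(
            [_aln(1, 33, "g", mm=[Mismatch(9, "G", "T")])] * 4 + [_aln(1, 33, "g")] * 6,
            "g", 76,
        )
        gly = build_coverage([_aln(1, 33, "g")] * 12, "g", 76)
        shallow = build_coverage([_aln(1, 33, "g")] * 3, "g", 76)
        kinds = {
            "tRNA_five_prime": {"Glu": glu, "Gly": gly, "Thr": shallow},
            "tRNA_three_prime": {},
            "rRNA": {},
        }
        rep = site_report({"s1": kinds}, min_coverage=10)
        t9 = rep[rep.site == "tRNA:9"].set_index("group")
        assert t9.loc["Glu", "mismatch_index"] == pytest.approx(40.0)
        assert t9.loc["Gly", "mismatch_index"] == pytest.approx(0.0)
        assert t9.loc["Thr", "mismatch_index"] is None or np.isnan(
            t9.loc["Thr", "mismatch_index"]
        )
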