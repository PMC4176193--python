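"""Marker classification, breakpoint inference, dosage, content, mosaicism."""

import math

import pytest
from statsmodels.stats.proportion import proportion_confint

from pericore import (
    CloneRecord,
    GenomicInterval,
    MarkerObservation,
    ProbeCall,
    characterize,
    classify_marker,
    infer_breakpoint,
    infer_dosage,
    mosaic_fraction,
    required_metaphases,
    size_content,
)
from pericore.markers import (
    ABSENT,
    DIMINISHED,
    DOUBLE,
    DosageConflictError,
    EUCHROMATIC,
    FLANKING,
    HETEROCHROMATIC_ONLY,
    INTERNAL_DELETION,
    SINGLE,
    UNDETERMINED,
    WITHIN_DIMINISHED,
)
from pericore.panels import Junction
from conftest import make_arm


def _clone(name, chrom, start, end):
    return CloneRecord(name, GenomicInterval(chrom, start, end))


def _call(arm, name, start, end, signal):
    return ProbeCall(_clone(name, arm.chrom, start, end), arm, signal)


class TestClassifyMarker:
    def test_all_absent_is_heterochromatic_only(self, arm22q):
        # a ring whose core probes on both arms show no signal
        arm16p = make_arm("chr16", "p", length=90_000_000, mid=36_000_000)
        arm16q = make_arm("chr16", "q", length=90_000_000, mid=36_000_000)
        obs = MarkerObservation(
            "p14",
            structure="ring",
            calls=[
                _call(arm16p, "RP11-488I20", 34_300_000, 34_480_000, ABSENT),
                _call(arm16q, "CTD-2382P11", 47_000_000, 47_180_000, ABSENT),
            ],
        )
        assert classify_marker(obs) == HETEROCHROMATIC_ONLY

    @pytest.mark.parametrize("signal", [SINGLE, DIMINISHED, DOUBLE])
    def test_any_signal_is_euchromatic(self, arm22q, signal):
        obs = MarkerObservation(
            "x", calls=[_call(arm22q, "A", 18_000_000, 18_180_000, signal)]
        )
        assert classify_marker(obs) == EUCHROMATIC

    def test_no_calls_undetermined(self):
        assert classify_marker(MarkerObservation("x")) == UNDETERMINED


class TestInferBreakpoint:
    def test_4p_flanking_hull(self, arm4p):
        # present RP11-178N2 then absent RP11-89F4 bound the 4p breakpoint at
        # the outer clone edges: chr4:44,621,297-45,736,237
        calls = [
            _call(arm4p, "RP11-178N2", 45_560_000, 45_736_237, SINGLE),
            _call(arm4p, "RP11-89F4", 44_621_297, 44_800_000, ABSENT),
        ]
        res = infer_breakpoint(calls)
        (bi,) = res.intervals
        assert bi.region == GenomicInterval("chr4", 44_621_297, 45_736_237)
        assert bi.basis == FLANKING and not bi.open_distal

    def test_11p_flanking_hull(self, arm11p):
        calls = [
            _call(arm11p, "RP11-746P9", 49_950_000, 50_111_641, SINGLE),
            _call(arm11p, "RP11-1062A8", 49_259_387, 49_420_000, ABSENT),
        ]
        (bi,) = infer_breakpoint(calls).intervals
        assert bi.region == GenomicInterval("chr11", 49_259_387, 50_111_641)

    def test_diminished_probe_bounds_breakpoint_within_clone(self, arm22q):
        calls = [_call(arm22q, "RP11-690P21", 17_900_000, 18_080_000, DIMINISHED)]
        (bi,) = infer_breakpoint(calls).intervals
        assert bi.basis == WITHIN_DIMINISHED
        assert bi.region == GenomicInterval("chr22", 17_900_000, 18_080_000)

    def test_all_present_is_open_distal(self, arm22q):
        calls = [
            _call(arm22q, "A", 18_000_000, 18_180_000, SINGLE),
            _call(arm22q, "B", 18_160_000, 18_340_000, SINGLE),
        ]
        (bi,) = infer_breakpoint(calls).intervals
        assert bi.open_distal
        assert bi.region.end == arm22q.extent.end
        assert bi.region.start == 18_160_000  # the last probe stays in the hull

    def test_internal_deletion_yields_two_flanked_intervals(self, arm22q):
        calls = [
            _call(arm22q, "A", 18_000_000, 18_180_000, SINGLE),
            _call(arm22q, "B", 18_200_000, 18_380_000, ABSENT),
            _call(arm22q, "C", 18_400_000, 18_580_000, SINGLE),
        ]
        res = infer_breakpoint(calls)
        assert INTERNAL_DELETION in res.flags
        closed = [b for b in res.intervals if not b.open_distal]
        assert len(closed) == 2
        assert closed[0].region == GenomicInterval("chr22", 18_000_000, 18_380_000)
        assert closed[1].region == GenomicInterval("chr22", 18_200_000, 18_580_000)

    def test_empty_and_mixed_arm_errors(self, arm4p, arm22q):
        with pytest.raises(ValueError):
            infer_breakpoint([])
        with pytest.raises(ValueError, match="mixed arms"):
            infer_breakpoint(
                [
                    _call(arm4p, "A", 45_000_000, 45_180_000, SINGLE),
                    _call(arm22q, "B", 18_000_000, 18_180_000, SINGLE),
                ]
            )


class TestInferDosage:
    def test_idic_double_signal_is_tetrasomy(self):
        # isodicentric 18: an enlarged (double) proximal probe signal
        arm18p = make_arm("chr18", "p", length=78_000_000, mid=17_500_000)
        segs = infer_dosage(
            [_call(arm18p, "RP11-749K13", 14_800_000, 14_980_000, DOUBLE)], "idic"
        )
        assert segs[0].marker_copies == 2
        assert segs[0].total_dosage == "tetrasomy"

    def test_idic_asymmetric_single_then_diminished(self, arm22q):
        # idic(22;22) with an equal (single) then diminished signal: a
        # trisomic segment ending inside the diminished clone
        segs = infer_dosage(
            [
                _call(arm22q, "RP11-1053O2", 17_500_000, 17_680_000, SINGLE),
                _call(arm22q, "RP11-690P21", 17_900_000, 18_080_000, DIMINISHED),
            ],
            "idic",
        )
        assert [s.marker_copies for s in segs] == [1, "partial"]
        assert segs[0].total_dosage == "trisomy"

    def test_ring_all_single_one_trisomy_segment(self, arm22q):
        segs = infer_dosage(
            [
                _call(arm22q, "A", 17_500_000, 17_680_000, SINGLE),
                _call(arm22q, "B", 17_660_000, 17_840_000, SINGLE),
            ],
            "ring",
        )
        assert len(segs) == 1
        assert segs[0].total_dosage == "trisomy"
        assert segs[0].region == GenomicInterval("chr22", 17_500_000, 17_840_000)

    def test_distal_copy_rise_without_deletion_is_conflict(self, arm22q):
        calls = [
            _call(arm22q, "A", 17_500_000, 17_680_000, ABSENT),
            _call(arm22q, "B", 17_700_000, 17_880_000, SINGLE),
        ]
        with pytest.raises(DosageConflictError):
            infer_dosage(calls, "ring")
        # the same pattern with the deletion flag is permitted
        segs = infer_dosage(calls, "ring", flags=[INTERNAL_DELETION])
        assert [s.marker_copies for s in segs] == [0, 1]

    def test_monotone_nonincreasing_along_arm(self, arm22q):
        segs = infer_dosage(
            [
                _call(arm22q, "A", 17_500_000, 17_680_000, DOUBLE),
                _call(arm22q, "B", 17_700_000, 17_880_000, SINGLE),
                _call(arm22q, "C", 17_900_000, 18_080_000, ABSENT),
            ],
            "idic",
        )
        copies = [s.marker_copies for s in segs]
        assert copies == [2, 1, 0]


class TestSizeContent:
    def test_heterochromatic_only_is_zero(self):
        assert size_content([], {}, HETEROCHROMATIC_ONLY) == (0.0, 0.0)

    def test_4p_refined_window_bounds(self, arm4p):
        # junction at 48.2 Mb, refined breakpoint window 45,518,972-45,736,237:
        # content between 2.46 and 2.68 Mb (hand-computed differences)
        calls = [
            _call(arm4p, "P", 45_736_237 - 170_000, 45_736_237, SINGLE),
            _call(arm4p, "A", 45_518_972, 45_518_972 + 170_000, ABSENT),
        ]
        res = infer_breakpoint(calls)
        junction = Junction(arm4p, 48_200_000, "defined")
        lo, hi = size_content([res], {"4p": junction}, EUCHROMATIC)
        assert round(lo, 2) == 2.46
        assert round(hi, 2) == 2.68

    def test_open_distal_max_is_infinite(self, arm22q):
        res = infer_breakpoint([_call(arm22q, "A", 18_000_000, 18_180_000, SINGLE)])
        junction = Junction(arm22q, 17_900_000, "defined")
        lo, hi = size_content([res], {"22q": junction}, EUCHROMATIC)
        assert math.isinf(hi)
        assert lo >= 0


class TestMosaicFraction:
    def test_full_mosaicism(self):
        frac, (lo, hi) = mosaic_fraction(16, 16)
        assert frac == 1.0 and hi == 1.0

    def test_zero_count(self):
        frac, (lo, hi) = mosaic_fraction(0, 16)
        assert frac == 0.0 and lo == 0.0
        ref_lo, ref_hi = proportion_confint(0, 16, alpha=0.05, method="beta")
        assert hi == pytest.approx(ref_hi, abs=1e-12)

    def test_half_symmetric_and_matches_oracle(self):
        frac, (lo, hi) = mosaic_fraction(8, 16)
        assert frac == 0.5
        assert lo == pytest.approx(1 - hi, abs=1e-12)
        ref_lo, ref_hi = proportion_confint(8, 16, alpha=0.05, method="beta")
        assert (lo, hi) == pytest.approx((ref_lo, ref_hi), abs=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            mosaic_fraction(1, 0)
        with pytest.raises(ValueError):
            mosaic_fraction(5, 4)


class TestRequiredMetaphases:
    def test_closed_form_values(self):
        assert required_metaphases(1.0, 0.95, floor=None) == 1
        assert required_metaphases(0.5, 0.95, floor=None) == 5
        assert required_metaphases(0.5, 0.95) == 16  # floored

    def test_monotone_in_mosaic_level(self):
        grid = [i / 101 for i in range(1, 101)]
        ns = [required_metaphases(m, 0.95, floor=None) for m in grid]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_undetectable_level_rejected(self):
        with pytest.raises(ValueError):
            required_metaphases(0.0, 0.95)


class TestCharacterizeInvariant:
    def test_het_only_iff_zero_content(self, sim_tracks, sim_panels, sim_junctions):
        from pericore.simulate import simulate_case

        for i in range(60):
            obs, _, truth = simulate_case(
                sim_tracks, sim_panels, seed=7000 + i, het_only=(i % 5 == 0)
            )
            chz = characterize(obs, sim_junctions)
            assert (chz.marker_class == HETEROCHROMATIC_ONLY) == (
                chz.content_max_mb == 0.0
            )
            assert chz.content_min_mb <= chz.content_max_mb
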