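"""Specificity screening, junction finding, and core-panel selection."""

import itertools
import random

import pytest

from pericore import (
    CloneRecord,
    GenomicInterval,
    HeterochromatinBlock,
    ScreenParams,
    arm_distance,
    find_junction,
    panel_stats,
    screen_clone,
    screen_library,
    screening_tally,
    select_core_panel,
    summarize_published_table,
    summarize_set,
)
from pericore.panels import (
    COMPLETE,
    CROSS_HYBRIDIZING,
    EXCLUDED,
    INCOMPLETE_NO_JUNCTION,
    INCOMPLETE_SEGDUP,
    Junction,
    PanelParams,
    SPECIFIC,
    UNAVAILABLE_NO_MAP,
)
from conftest import make_arm


# --------------------------------------------------------------------------
# Junction finding

class TestFindJunction:
    def test_p_arm_junction_is_het_start(self):
        # mirrors the 4p arm whose heterochromatin starts at 48.2 Mb
        arm = make_arm("chr4", "p", length=191_154_276, mid=50_400_000)
        blocks = [
            HeterochromatinBlock(GenomicInterval("chr4", 48_200_000, 50_400_000), "p")
        ]
        j = find_junction(arm, blocks)
        assert j.defined and j.position == 48_200_000

    def test_q_arm_junction_is_het_end(self):
        arm = make_arm("chr4", "q", length=191_154_276, mid=50_400_000)
        blocks = [
            HeterochromatinBlock(GenomicInterval("chr4", 50_400_000, 52_700_000), "q")
        ]
        assert find_junction(arm, blocks).position == 52_700_000

    def test_missing_block_is_undefined_not_error(self):
        arm = make_arm("chr1", "p")
        j = find_junction(arm, [])
        assert not j.defined and j.status == "undefined_no_junction"

    def test_planted_junctions_recovered(self, sim_tracks, sim_junctions):
        # the generator anchors every het block at the arm root, so the
        # junction equals the block edge facing the euchromatin
        for name, j in sim_junctions.items():
            arm = sim_tracks.arms[name]
            blocks = sim_tracks.het_blocks_for(arm)
            expected = (
                min(b.region.start for b in blocks)
                if arm.arm == "p"
                else max(b.region.end for b in blocks)
            )
            assert j.position == expected


# --------------------------------------------------------------------------
# Screening

def _oracle_label(clone: CloneRecord, params: ScreenParams) -> str:
    """Independent restatement of the three screening rules."""
    if any(a.chrom != clone.primary.chrom for a in clone.alternates):
        return EXCLUDED
    same = [a for a in clone.alternates if a.chrom == clone.primary.chrom]
    if len(same) > params.max_alternate_placements:
        return CROSS_HYBRIDIZING
    if clone.segdup_fraction > params.max_segdup_fraction:
        return CROSS_HYBRIDIZING
    return SPECIFIC


def _random_library(rng: random.Random, n: int) -> list[CloneRecord]:
    clones = []
    for i in range(n):
        chrom = f"chr{rng.randint(1, 4)}"
        start = rng.randint(0, 10**7)
        alts = []
        for _ in range(rng.randint(0, 2)):
            alt_chrom = f"chr{rng.randint(1, 4)}"
            a = rng.randint(0, 10**7)
            alts.append(GenomicInterval(alt_chrom, a, a + 150_000))
        clones.append(
            CloneRecord(
                f"C{i:03d}",
                GenomicInterval(chrom, start, start + 170_000),
                tuple(alts),
                segdup_fraction=rng.random(),
            )
        )
    return clones


class TestScreening:
    def test_single_clean_placement_is_specific(self):
        c = CloneRecord("A", GenomicInterval("chr1", 0, 100_000))
        assert screen_clone(c).label == SPECIFIC

    def test_off_chromosome_placement_is_excluded(self):
        c = CloneRecord(
            "A",
            GenomicInterval("chr1", 0, 100_000),
            (GenomicInterval("chr2", 0, 100_000),),
        )
        call = screen_clone(c)
        assert call.label == EXCLUDED
        assert "off_chromosome_placement" in call.reasons

    def test_matches_independent_rule_evaluator(self):
        rng = random.Random(7)
        params = ScreenParams()
        for clone in _random_library(rng, 200):
            assert screen_clone(clone, params).label == _oracle_label(clone, params)

    def test_order_invariance(self):
        rng = random.Random(3)
        lib = _random_library(rng, 60)
        labels = {n: c.label for n, c in screen_library(lib).items()}
        rng.shuffle(lib)
        assert {n: c.label for n, c in screen_library(lib).items()} == labels

    def test_tally_from_printed_counts(self):
        t = screening_tally(323, 163, 75)
        assert t["n_assayed"] == 561
        assert t["n_retained"] == 486
        assert t["pct_excluded"] == 13.4


# --------------------------------------------------------------------------
# Core-panel selection

def _q_arm():
    return make_arm("chr2", "q", length=200_000_000, mid=50_000_000)


def _tiling_library(junction: int, n: int = 6, width: int = 180_000, overlap: int = 20_000):
    clones = []
    pos = junction
    for i in range(n):
        clones.append(CloneRecord(f"T{i}", GenomicInterval("chr2", pos, pos + width)))
        pos += width - overlap
    return clones


class TestSelectCorePanel:
    def test_planted_contiguous_tiling_covers_target(self):
        arm = _q_arm()
        j = Junction(arm, 60_000_000, "defined")
        lib = _tiling_library(60_000_000)
        panel = select_core_panel(arm, j, lib)
        assert panel.status == COMPLETE
        st = panel_stats(panel)
        assert st.d_het_prox == 0.0
        assert st.core_span >= 0.70
        # zero internal gaps
        for a, b in zip(panel.clones, panel.clones[1:]):
            assert b.primary.start <= a.primary.end

    def test_distant_proximal_clone_after_screening_exclusions(self):
        # clones nearest the junction are excluded for off-target placements,
        # leaving the first usable clone 0.76 Mb out (a segdup-blocked arm)
        arm = _q_arm()
        j = Junction(arm, 60_000_000, "defined")
        bad = CloneRecord(
            "BAD",
            GenomicInterval("chr2", 60_000_000, 60_180_000),
            (GenomicInterval("chr3", 0, 180_000),),
        )
        lib = [bad] + _tiling_library(60_760_000)
        panel = select_core_panel(arm, j, lib)
        assert panel.status == INCOMPLETE_SEGDUP
        assert panel_stats(panel).d_het_prox == 0.76

    def test_empty_library_is_unavailable(self):
        arm = _q_arm()
        panel = select_core_panel(arm, Junction(arm, 60_000_000, "defined"), [])
        assert panel.status == UNAVAILABLE_NO_MAP
        assert panel.clones == []

    def test_undefined_junction_status(self):
        arm = _q_arm()
        panel = select_core_panel(
            arm, Junction(arm, None, "undefined_no_junction"), _tiling_library(60_000_000)
        )
        assert panel.status == INCOMPLETE_NO_JUNCTION
        assert panel.clones  # selection still proceeds from the arm root


# --------------------------------------------------------------------------
# Greedy vs exhaustive minimal cover

def _min_cover_bruteforce(clones, window_start, window_end) -> int:
    """Smallest number of clones covering [window_start, window_end)."""
    best = None
    ivs = [c.primary for c in clones]
    for k in range(1, len(ivs) + 1):
        if best is not None:
            break
        for combo in itertools.combinations(ivs, k):
            frontier = window_start
            for iv in sorted(combo, key=lambda v: v.start):
                if iv.start > frontier:
                    break
                frontier = max(frontier, iv.end)
            if frontier >= window_end:
                best = k
                break
    return best


def _coverable_library(rng: random.Random, junction: int, target: int):
    """A random library guaranteed to admit a cover of the target window."""
    clones = []
    pos = junction
    i = 0
    while pos < junction + target:
        w = rng.randint(120_000, 250_000)
        clones.append(CloneRecord(f"G{i}", GenomicInterval("chr2", pos, pos + w)))
        pos += w - rng.randint(1, 60_000)
        i += 1
    for j in range(rng.randint(0, 8)):
        s = junction + rng.randint(0, target)
        w = rng.randint(80_000, 300_000)
        clones.append(CloneRecord(f"R{j}", GenomicInterval("chr2", s, s + w)))
    return clones


def greedy_matches_bruteforce(n_libraries: int, seed: int) -> None:
    rng = random.Random(seed)
    arm = _q_arm()
    junction = Junction(arm, 60_000_000, "defined")
    target = 700_000
    params = PanelParams(target_span_bp=target, max_gap_bp=0, max_clones=99, min_clones=1)
    for _ in range(n_libraries):
        lib = _coverable_library(rng, 60_000_000, target)
        if len(lib) > 15:
            continue
        panel = select_core_panel(arm, junction, lib, params)
        brute = _min_cover_bruteforce(lib, 60_000_000, 60_000_000 + target)
        assert brute is not None
        assert len(panel.clones) == brute


class TestGreedyOptimality:
    def test_greedy_equals_bruteforce_minimum(self):
        greedy_matches_bruteforce(40, seed=5)

    def test_gap_monotonicity(self):
        rng = random.Random(9)
        arm = _q_arm()
        junction = Junction(arm, 60_000_000, "defined")
        for _ in range(30):
            lib = _coverable_library(rng, 60_000_000, 700_000)
            counts = []
            for gap in (0, 25_000, 50_000, 100_000):
                p = select_core_panel(
                    arm, junction, lib,
                    PanelParams(max_gap_bp=gap, max_clones=99, min_clones=1),
                )
                counts.append(len(p.clones))
            assert counts == sorted(counts, reverse=True) or all(
                a >= b for a, b in zip(counts, counts[1:])
            )


# --------------------------------------------------------------------------
# Stats and summaries

class TestPanelStats:
    def test_single_clone_panel_span_equals_clone_width(self):
        arm = _q_arm()
        lib = [CloneRecord("S", GenomicInterval("chr2", 60_000_000, 60_180_000))]
        panel = select_core_panel(arm, Junction(arm, 60_000_000, "defined"), lib)
        assert panel_stats(panel).core_span == 0.18

    def test_stats_match_hand_computed_arm_distances(self, sim_tracks, sim_panels, sim_junctions):
        for name, panel in sim_panels.items():
            if not panel.clones:
                continue
            arm = panel.arm
            st = panel_stats(panel)
            prox = panel.clones[0]
            dist = panel.clones[-1]
            expected_span = arm_distance(
                arm, prox.proximal_edge(arm), dist.distal_edge(arm)
            ) / 1e6
            assert st.core_span == pytest.approx(expected_span, abs=0.005)
            expected_d = max(
                0, arm_distance(arm, panel.junction, prox.proximal_edge(arm))
            ) / 1e6
            assert st.d_het_prox == pytest.approx(expected_d, abs=0.005)


class TestSummaries:
    def test_published_table_summary(self):
        s = summarize_published_table()
        assert s.n_panels == 43
        assert s.n_complete == 35
        assert s.mean_core_span == 0.73

    def test_empty_input(self):
        s = summarize_set([])
        assert s.n_panels == 0 and s.mean_core_span is None

    def test_sim_panels_all_anchored(self, sim_panels):
        s = summarize_set(list(sim_panels.values()))
        assert s.n_panels == len(sim_panels)
        assert s.n_complete == s.n_panels  # clean tiling: every arm completes
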