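"""Junction-bridging core-panel design for pericentromeric FISH probe sets.

A *core panel* is an ordered tiling of BAC clones anchored at the
heterochromatin/euchromatin junction of one chromosome arm, covering the
most proximal euchromatic sequence (~0.7 Mb by default).  This module
screens clone libraries for hybridization specificity, selects the tiling
greedily (proximal-anchored farthest-reach, which is optimal for interval
cover), and computes the bookkeeping statistics of a panel set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome import (
    ChromosomeArm,
    CloneRecord,
    HeterochromatinBlock,
    arm_distance,
    _round_half_up,
)

__all__ = [
    "ScreenParams",
    "SpecificityCall",
    "PanelParams",
    "CorePanel",
    "PanelStats",
    "PanelSetSummary",
    "Junction",
    "find_junction",
    "screen_clone",
    "screen_library",
    "select_core_panel",
    "panel_stats",
    "summarize_set",
    "screening_tally",
    "published_core_table",
    "summarize_published_table",
]

SPECIFIC = "specific"
CROSS_HYBRIDIZING = "cross_hybridizing"
EXCLUDED = "excluded"

COMPLETE = "complete"
INCOMPLETE_NO_JUNCTION = "incomplete_no_junction"
INCOMPLETE_SEGDUP = "incomplete_segdup"
UNAVAILABLE_NO_MAP = "unavailable_no_map"


# --------------------------------------------------------------------------
# Junction finding

@dataclass(frozen=True)
class Junction:
    """The heterochromatin/euchromatin boundary of one arm, if annotated."""

    arm: ChromosomeArm
    position: int | None
    status: str  # "defined" | "undefined_no_junction"

    @property
    def defined(self) -> bool:
        return self.position is not None


def find_junction(
    arm: ChromosomeArm, blocks: Iterable[HeterochromatinBlock]
) -> Junction:
    """Locate the het/eu junction of an arm from its heterochromatin blocks.

    On a p arm euchromatin lies at smaller coordinates, so the junction is
    the start of the arm's heterochromatin; on a q arm it is the end.  Arms
    with no annotated block get an undefined junction (a value, not an
    error) — mirroring reference-sequence gaps at several human arm roots.
    """
    own = [
        b
        for b in blocks
        if b.region.chrom == arm.chrom and b.arm_side == arm.arm
    ]
    if not own:
        return Junction(arm, None, "undefined_no_junction")
    if arm.arm == "p":
        pos = min(b.region.start for b in own)
    else:
        pos = max(b.region.end for b in own)
    return Junction(arm, pos, "defined")


# --------------------------------------------------------------------------
# Specificity screening

@dataclass(frozen=True)
class ScreenParams:
    """Thresholds for calling a clone usable as a locus-specific probe."""

    max_segdup_fraction: float = 0.5
    max_alternate_placements: int = 0


@dataclass(frozen=True)
class SpecificityCall:
    clone: CloneRecord
    label: str
    reasons: tuple[str, ...] = ()


def screen_clone(clone: CloneRecord, params: ScreenParams = ScreenParams()) -> SpecificityCall:
    """Label a clone specific / cross-hybridizing / excluded.

    A placement on a different chromosome than the primary mimics a wrong
    chromosomal localization and excludes the clone outright.  Alternate
    placements on the same chromosome, or heavy segmental-duplication
    coverage, make the clone cross-hybridizing but still mappable.
    """
    reasons: list[str] = []
    if any(alt.chrom != clone.primary.chrom for alt in clone.alternates):
        reasons.append("off_chromosome_placement")
        return SpecificityCall(clone, EXCLUDED, tuple(reasons))
    n_same = sum(alt.chrom == clone.primary.chrom for alt in clone.alternates)
    if n_same > params.max_alternate_placements:
        reasons.append("same_chromosome_alternate")
    if clone.segdup_fraction > params.max_segdup_fraction:
        reasons.append("segdup_fraction")
    if reasons:
        return SpecificityCall(clone, CROSS_HYBRIDIZING, tuple(reasons))
    return SpecificityCall(clone, SPECIFIC, ())


def screen_library(
    clones: Iterable[CloneRecord], params: ScreenParams = ScreenParams()
) -> dict[str, SpecificityCall]:
    return {c.name: screen_clone(c, params) for c in clones}


def screening_tally(n_specific: int, n_cross: int, n_excluded: int) -> dict[str, float]:
    """Bookkeeping over screening outcome counts.

    Returns the totals and percentages a screening campaign reports: probes
    assayed, probes retained (specific + cross-hybridizing), and the share
    of each label among the assayed probes (one decimal).
    """
    total = n_specific + n_cross + n_excluded
    if total <= 0:
        raise ValueError("no probes assayed")
    pct = lambda k: _round_half_up(100.0 * k / total, 1)
    return {
        "n_assayed": total,
        "n_retained": n_specific + n_cross,
        "pct_specific": pct(n_specific),
        "pct_cross_hybridizing": pct(n_cross),
        "pct_excluded": pct(n_excluded),
    }


# --------------------------------------------------------------------------
# Core-panel selection

@dataclass(frozen=True)
class PanelParams:
    """Tiling targets: cover ~0.7 Mb of proximal euchromatin with 3-7 clones."""

    target_span_bp: int = 700_000
    max_gap_bp: int = 50_000
    min_clones: int = 3
    max_clones: int = 7
    #: A panel only counts as junction-anchored when its proximal clone
    #: overlaps or abuts the junction within this slack.
    proximal_slack_bp: int = 0


@dataclass
class CorePanel:
    arm: ChromosomeArm
    junction: int | None
    clones: list[CloneRecord]
    status: str
    status_note: str = ""

    @property
    def proximal_clone(self) -> CloneRecord | None:
        return self.clones[0] if self.clones else None

    @property
    def distal_clone(self) -> CloneRecord | None:
        return self.clones[-1] if self.clones else None


def _d_het_prox_bp(arm: ChromosomeArm, junction: int, clone: CloneRecord) -> int:
    """Distance from the junction to a clone's proximal edge, floored at 0.

    Zero for clones that overlap or abut the junction (the panel straddles
    the boundary, the common case in a completed panel).
    """
    return max(0, arm_distance(arm, junction, clone.proximal_edge(arm)))


def select_core_panel(
    arm: ChromosomeArm,
    junction: Junction,
    library: Sequence[CloneRecord],
    params: PanelParams = PanelParams(),
    screening: dict[str, SpecificityCall] | None = None,
) -> CorePanel:
    """Select a junction-anchored greedy tiling of the proximal euchromatin.

    The proximal clone is the eligible clone nearest the junction; each
    subsequent clone is the one reaching farthest distally among candidates
    whose proximal edge lies within ``max_gap_bp`` of the current frontier.
    Greedy farthest-reach selection yields a minimum-cardinality cover of
    the spanned interval.  Clones screened as *excluded* are never eligible.
    """
    if screening is None:
        screening = screen_library(library)
    excluded_names = {n for n, c in screening.items() if c.label == EXCLUDED}

    def on_arm(c: CloneRecord) -> bool:
        return c.primary.chrom == arm.chrom and c.primary.overlaps(arm.extent)

    eligible = [c for c in library if on_arm(c) and c.name not in excluded_names]
    excluded_on_arm = [c for c in library if on_arm(c) and c.name in excluded_names]

    anchor = junction.position if junction.defined else arm.proximal_pos

    if not eligible:
        return CorePanel(arm, junction.position, [], UNAVAILABLE_NO_MAP,
                         "no mappable clone on the arm")

    # proximal anchor: minimize distance from the junction; among ties take
    # the farthest distal reach (keeps the greedy cover minimal), then name
    eligible.sort(
        key=lambda c: (
            _d_het_prox_bp(arm, anchor, c),
            -arm_distance(arm, anchor, c.distal_edge(arm)),
            c.name,
        )
    )
    first = eligible[0]
    chosen = [first]
    frontier = first.distal_edge(arm)
    span_start = first.proximal_edge(arm)

    def span() -> int:
        return arm_distance(arm, span_start, frontier)

    while span() < params.target_span_bp and len(chosen) < params.max_clones:
        picked = set(c.name for c in chosen)
        candidates = [
            c
            for c in eligible
            if c.name not in picked
            and arm_distance(arm, frontier, c.proximal_edge(arm)) <= params.max_gap_bp
            and arm_distance(arm, frontier, c.distal_edge(arm)) > 0
        ]
        if not candidates:
            break
        candidates.sort(
            key=lambda c: (-arm_distance(arm, frontier, c.distal_edge(arm)), c.name)
        )
        nxt = candidates[0]
        chosen.append(nxt)
        frontier = nxt.distal_edge(arm)

    d_prox = _d_het_prox_bp(arm, anchor, first)
    target_met = span() >= params.target_span_bp
    anchored = junction.defined and d_prox <= params.proximal_slack_bp
    count_ok = params.min_clones <= len(chosen) <= params.max_clones

    if not junction.defined:
        status, note = INCOMPLETE_NO_JUNCTION, "no heterochromatin/euchromatin junction annotated"
    elif anchored and target_met and count_ok:
        status, note = COMPLETE, ""
    elif excluded_on_arm and any(
        _d_het_prox_bp(arm, anchor, c) < d_prox for c in excluded_on_arm
    ):
        status, note = INCOMPLETE_SEGDUP, (
            "proximal clones removed by specificity screening"
        )
    else:
        status = INCOMPLETE_SEGDUP
        note = "target span not reached" if not target_met else "proximal anchor gap"
    return CorePanel(arm, junction.position, chosen, status, note)


# --------------------------------------------------------------------------
# Panel statistics

@dataclass(frozen=True)
class PanelStats:
    """Bookkeeping distances of one panel, in Mb (2 decimals)."""

    d_het_prox: float | None
    core_span: float | None


def panel_stats(panel: CorePanel) -> PanelStats:
    """Junction-to-proximal-clone distance and proximal-to-distal core span.

    Both are arm-oriented distances in Mb rounded to 2 decimals; the
    junction distance is floored at zero for clones straddling the boundary.
    """
    if not panel.clones:
        return PanelStats(None, None)
    arm = panel.arm
    prox = panel.proximal_clone
    dist = panel.distal_clone
    d_het = None
    if panel.junction is not None:
        d_het = _round_half_up(
            _d_het_prox_bp(arm, panel.junction, prox) / 1e6, 2
        )
    span = _round_half_up(
        arm_distance(arm, prox.proximal_edge(arm), dist.distal_edge(arm)) / 1e6, 2
    )
    return PanelStats(d_het, span)


@dataclass(frozen=True)
class PanelSetSummary:
    n_panels: int
    n_complete: int
    mean_core_span: float | None
    status_counts: dict[str, int] = field(default_factory=dict)


def summarize_set(
    panels: Sequence[CorePanel], spans: Sequence[float] | None = None
) -> PanelSetSummary:
    """Summarize a panel set: status counts and the mean core span in Mb.

    The mean is taken over panels with a distinct proximal and distal clone
    (single-clone and empty panels have no spanned core).  ``spans`` may
    supply precomputed span values instead, e.g. from a published table.
    """
    counts: dict[str, int] = {}
    for p in panels:
        counts[p.status] = counts.get(p.status, 0) + 1
    if spans is None:
        spans = [
            panel_stats(p).core_span for p in panels if len(p.clones) >= 2
        ]
    spans = [s for s in spans if s is not None]
    mean = _round_half_up(sum(spans) / len(spans), 2) if spans else None
    return PanelSetSummary(
        n_panels=len(panels),
        n_complete=counts.get(COMPLETE, 0),
        mean_core_span=mean,
        status_counts=counts,
    )


def design_all(
    tracks,
    params: PanelParams = PanelParams(),
    screen_params: ScreenParams = ScreenParams(),
) -> tuple[dict[str, Junction], dict[str, CorePanel]]:
    """Screen the library and design a core panel for every non-acrocentric arm."""
    screening = screen_library(tracks.clones, screen_params)
    junctions: dict[str, Junction] = {}
    panels: dict[str, CorePanel] = {}
    for name, arm in tracks.arms.items():
        if arm.acrocentric_p:
            continue
        junction = find_junction(arm, tracks.het_blocks)
        junctions[name] = junction
        panels[name] = select_core_panel(
            arm, junction, tracks.clones, params, screening
        )
    return junctions, panels


# --------------------------------------------------------------------------
# Published core-panel table
#
# The printed per-arm summary of the 43 human pericentromeric core panels:
# heterochromatic-region start/end (Mb), junction-to-proximal-clone distance
# (Mb), proximal-to-distal core span (Mb), and the panel status.  Clone bp
# extents live only in supplementary material, so the bookkeeping columns
# are carried as data.  Spans of None mean no distal core clone was placed.

@dataclass(frozen=True)
class PublishedPanelRow:
    arm: str
    het_start_mb: float | None
    het_end_mb: float | None
    d_het_prox_mb: float | None
    core_span_mb: float | None
    status: str


_T = [
    # (arm, het_start, het_end, d_het_prox, core_span, status)
    ("1p", 121.5, None, 0.015, 0.98, INCOMPLETE_NO_JUNCTION),
    ("1q", None, 142.6, 0.76, 1.46, INCOMPLETE_SEGDUP),
    ("2p", 90.5, None, 0.0, 0.61, COMPLETE),
    ("2q", None, 96.8, 0.0, 0.96, COMPLETE),
    ("3p", 87.9, None, 0.0, 0.71, COMPLETE),
    ("3q", None, 93.9, 0.0, 0.87, COMPLETE),
    ("4p", 48.2, None, 0.0, 0.88, COMPLETE),
    ("4q", None, 52.7, 0.0, 0.76, COMPLETE),
    ("5p", 46.1, None, 0.0, 0.91, COMPLETE),
    ("5q", None, 50.7, 0.0, 0.33, COMPLETE),
    ("6p", 58.7, None, 0.0, 1.02, COMPLETE),
    ("6q", None, 63.3, 0.0, 0.30, COMPLETE),
    ("7p", 58.0, None, 0.0, 0.66, COMPLETE),
    ("7q", None, 61.7, 0.0, 0.84, COMPLETE),
    ("8p", 43.1, None, 0.0, 0.79, COMPLETE),
    ("8q", None, 48.1, 0.0, 0.56, COMPLETE),
    ("9p", 47.3, None, 0.37, 0.64, INCOMPLETE_SEGDUP),
    ("9q", None, 65.9, 0.0, 0.49, COMPLETE),
    ("10p", 38.0, None, 0.0, 0.58, COMPLETE),
    ("10q", None, 42.3, 0.08, 1.32, INCOMPLETE_NO_JUNCTION),
    ("11p", 51.6, None, 0.06, 1.00, INCOMPLETE_NO_JUNCTION),
    ("11q", None, 55.7, 0.0, 0.85, COMPLETE),
    ("12p", 33.3, None, 0.0, 0.48, COMPLETE),
    ("12q", None, 38.2, 0.0, 0.68, COMPLETE),
    ("13q", None, 19.5, 0.0, 0.32, COMPLETE),
    ("14q", None, 19.1, 0.0, 0.90, COMPLETE),
    ("15q", None, 20.7, 0.0, 0.34, COMPLETE),
    ("16p", 34.6, None, 0.0, 0.32, COMPLETE),
    ("16q", None, 47.0, 0.0, 0.36, COMPLETE),
    ("17p", 22.2, None, 0.0, 0.51, COMPLETE),
    ("17q", None, 25.8, 0.0, 0.52, COMPLETE),
    ("18p", 15.4, None, 0.0, 0.52, COMPLETE),
    ("18q", None, 19.0, 0.0, 0.66, COMPLETE),
    ("19p", 24.4, None, 0.0, 0.86, COMPLETE),
    ("19q", None, 28.6, 0.0, 0.95, COMPLETE),
    ("20p", 25.6, None, 0.0, 0.49, COMPLETE),
    ("20q", None, 29.4, 0.02, 1.17, INCOMPLETE_NO_JUNCTION),
    ("21q", None, 14.3, 0.13, 0.93, INCOMPLETE_NO_JUNCTION),
    ("22q", None, 17.9, 0.0, 0.71, COMPLETE),
    ("Xp", 58.1, None, 0.0, 0.96, COMPLETE),
    ("Xq", None, 63.0, 0.0, 0.54, COMPLETE),
    ("Yp", 11.6, None, 1.50, None, UNAVAILABLE_NO_MAP),
    ("Yq", None, 13.4, 0.0, 1.1, COMPLETE),
]


def published_core_table() -> list[PublishedPanelRow]:
    """The per-arm bookkeeping table of the 43 human core panels."""
    return [PublishedPanelRow(*row) for row in _T]


def summarize_published_table(
    rows: Sequence[PublishedPanelRow] | None = None,
) -> PanelSetSummary:
    """Recompute the panel-set summary from the published per-arm table."""
    if rows is None:
        rows = published_core_table()
    counts: dict[str, int] = {}
    for r in rows:
        counts[r.status] = counts.get(r.status, 0) + 1
    spans = [r.core_span_mb for r in rows if r.core_span_mb is not None]
    mean = _round_half_up(sum(spans) / len(spans), 2) if spans else None
    return PanelSetSummary(
        n_panels=len(rows),
        n_complete=counts.get(COMPLETE, 0),
        mean_core_span=mean,
        status_counts=counts,
    )
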