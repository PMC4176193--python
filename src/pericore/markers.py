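"""Characterization of small supernumerary marker chromosomes from FISH calls.

Given ordered per-probe signal calls on a marker chromosome (absent /
diminished / single / double), this module classifies the marker as
heterochromatic-only or euchromatic, maps per-arm breakpoint intervals
between the flanking present/absent probes, assigns per-segment dosage,
bounds the euchromatic DNA content, and estimates the mosaic fraction from
metaphase counts with an exact binomial confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import beta as _beta

from .genome import (
    ChromosomeArm,
    CloneRecord,
    GenomicInterval,
    arm_distance,
)
from .panels import Junction

__all__ = [
    "ProbeCall",
    "MarkerObservation",
    "BreakpointInterval",
    "SegmentDosage",
    "MarkerCharacterization",
    "ArmBreakpointResult",
    "DosageConflictError",
    "classify_marker",
    "infer_breakpoint",
    "infer_dosage",
    "size_content",
    "mosaic_fraction",
    "required_metaphases",
    "characterize",
    "SIGNALS",
]

ABSENT = "absent"
DIMINISHED = "diminished"
SINGLE = "single"
DOUBLE = "double"
SIGNALS = (ABSENT, DIMINISHED, SINGLE, DOUBLE)
_PRESENT = (SINGLE, DOUBLE)

HETEROCHROMATIC_ONLY = "heterochromatic_only"
EUCHROMATIC = "euchromatic"
UNDETERMINED = "undetermined"

FLANKING = "flanking_probes"
WITHIN_DIMINISHED = "within_diminished_probe"
ACGH_REFINED = "acgh_refined"

INTERNAL_DELETION = "internal_deletion"


class DosageConflictError(ValueError):
    """Copy number increases distally without an internal-deletion flag."""


@dataclass(frozen=True)
class ProbeCall:
    probe: CloneRecord
    arm: ChromosomeArm
    signal: str

    def __post_init__(self) -> None:
        if self.signal not in SIGNALS:
            raise ValueError(f"unknown signal {self.signal!r}")
        if self.probe.primary.chrom != self.arm.chrom:
            raise ValueError(
                f"probe {self.probe.name} not on chromosome {self.arm.chrom}"
            )


@dataclass
class MarkerObservation:
    """One marker-chromosome case: structure hint, calls, metaphase counts."""

    case_id: str
    structure: str = "unknown"  # unknown | ring | idic | minute
    calls: list[ProbeCall] = field(default_factory=list)
    n_metaphases_total: int = 0
    n_metaphases_with_marker: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_metaphases_with_marker <= self.n_metaphases_total):
            raise ValueError("metaphase counts inconsistent")

    def calls_by_arm(self) -> dict[str, list[ProbeCall]]:
        out: dict[str, list[ProbeCall]] = {}
        for c in self.calls:
            out.setdefault(c.arm.name, []).append(c)
        return out


@dataclass(frozen=True)
class BreakpointInterval:
    arm: ChromosomeArm
    region: GenomicInterval
    basis: str  # flanking_probes | within_diminished_probe | acgh_refined
    open_distal: bool = False

    def __post_init__(self) -> None:
        if self.open_distal and self.basis != FLANKING:
            raise ValueError("open_distal breakpoints must be probe-flanked")


@dataclass(frozen=True)
class SegmentDosage:
    region: GenomicInterval
    marker_copies: int | str  # 0 | 1 | 2 | "partial"
    total_dosage: str  # disomy | trisomy | tetrasomy | partial

    @staticmethod
    def label_for(copies: int | str) -> str:
        return {0: "disomy", 1: "trisomy", 2: "tetrasomy"}.get(copies, "partial")


@dataclass
class MarkerCharacterization:
    case_id: str
    marker_class: str  # heterochromatic_only | euchromatic | undetermined
    breakpoints: list[BreakpointInterval] = field(default_factory=list)
    segments: list[SegmentDosage] = field(default_factory=list)
    content_min_mb: float = 0.0
    content_max_mb: float = 0.0  # math.inf when open-ended
    mosaic_fraction: float | None = None
    mosaic_ci: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# Ordering helpers

def _ordered(calls: list[ProbeCall]) -> list[ProbeCall]:
    """Order calls proximal -> distal along their arm; ties broken by name."""
    arms = {c.arm.name for c in calls}
    if len(arms) != 1:
        raise ValueError(f"calls from mixed arms: {sorted(arms)}")
    arm = calls[0].arm
    ref = arm.proximal_pos
    return sorted(
        calls,
        key=lambda c: (
            arm_distance(arm, ref, c.probe.proximal_edge(arm)),
            c.probe.name,
        ),
    )


def _hull(arm: ChromosomeArm, *positions: int) -> GenomicInterval:
    return GenomicInterval(arm.chrom, min(positions), max(positions))


# --------------------------------------------------------------------------
# Classification

def classify_marker(obs: MarkerObservation) -> str:
    """Heterochromatic-only iff every euchromatic-probe call is absent."""
    if not obs.calls:
        return UNDETERMINED
    if all(c.signal == ABSENT for c in obs.calls):
        return HETEROCHROMATIC_ONLY
    return EUCHROMATIC


# --------------------------------------------------------------------------
# Breakpoint inference

@dataclass
class ArmBreakpointResult:
    arm: ChromosomeArm
    intervals: list[BreakpointInterval]
    flags: list[str] = field(default_factory=list)


def infer_breakpoint(
    calls: list[ProbeCall], junction: Junction | None = None
) -> ArmBreakpointResult:
    """Map the breakpoint interval(s) on one arm from ordered probe calls.

    The breakpoint between the most distal present probe P and the most
    proximal absent probe distal of it, A, is bounded by the convex hull of
    both clone extents — conservative in both directions.  A diminished
    signal places the breakpoint inside that clone.  When every probe is
    present the breakpoint is open-ended beyond the most distal probe.  An
    absent probe between present probes marks an internal deletion and
    yields one interval per transition.
    """
    if not calls:
        raise ValueError("no calls on arm")
    ordered = _ordered(calls)
    arm = ordered[0].arm

    intervals: list[BreakpointInterval] = []
    flags: list[str] = []

    # Internal deletion: a present probe distal of an absent one.
    state = [(c, c.signal != ABSENT) for c in ordered]
    for i in range(1, len(state)):
        if state[i][1] and not state[i - 1][1] and any(p for _, p in state[:i]):
            if INTERNAL_DELETION not in flags:
                flags.append(INTERNAL_DELETION)

    # Diminished probes: breakpoint lies within the clone.
    for c in ordered:
        if c.signal == DIMINISHED:
            intervals.append(
                BreakpointInterval(arm, c.probe.primary, WITHIN_DIMINISHED)
            )

    # Present/absent transitions (convex hull of the flanking clones).  The
    # reverse transition bounds the distal edge of an internal deletion.
    for i in range(1, len(ordered)):
        prev, cur = ordered[i - 1], ordered[i]
        fwd = prev.signal in _PRESENT and cur.signal == ABSENT
        rev = (
            prev.signal == ABSENT
            and cur.signal in _PRESENT
            and any(c.signal in _PRESENT for c in ordered[:i])
        )
        if fwd or rev:
            region = _hull(
                arm,
                prev.probe.proximal_edge(arm),
                prev.probe.distal_edge(arm),
                cur.probe.proximal_edge(arm),
                cur.probe.distal_edge(arm),
            )
            intervals.append(BreakpointInterval(arm, region, FLANKING))

    if intervals and ordered[-1].signal in _PRESENT and INTERNAL_DELETION in flags:
        # content resumes distal of a deletion and runs past the last probe
        last = ordered[-1]
        intervals.append(
            BreakpointInterval(
                arm,
                _hull(arm, last.probe.proximal_edge(arm), arm.distal_pos),
                FLANKING,
                open_distal=True,
            )
        )

    if not intervals:
        if all(c.signal in _PRESENT for c in ordered):
            # Open distal: the breakpoint lies in or beyond the most distal
            # probe (a full signal tolerates a sub-probe distal loss), so the
            # hull keeps that clone's extent, conservatively.
            last = ordered[-1]
            region = _hull(arm, last.probe.proximal_edge(arm), arm.distal_pos)
            intervals.append(
                BreakpointInterval(arm, region, FLANKING, open_distal=True)
            )
        else:
            # All absent: content, if any, lies proximal of the first probe.
            first = ordered[0]
            ref = junction.position if junction and junction.defined else arm.proximal_pos
            region = _hull(arm, ref, first.probe.proximal_edge(arm))
            intervals.append(BreakpointInterval(arm, region, FLANKING))
    return ArmBreakpointResult(arm, intervals, flags)


# --------------------------------------------------------------------------
# Dosage

_COPIES = {DOUBLE: 2, SINGLE: 1, DIMINISHED: "partial", ABSENT: 0}


def infer_dosage(
    calls: list[ProbeCall],
    structure: str = "unknown",
    flags: list[str] | None = None,
) -> list[SegmentDosage]:
    """Per-segment marker copy number along one arm.

    Signals map to marker copies (double=2, single=1, diminished=partial,
    absent=0); the total dosage adds the two constitutive homologs.
    Consecutive probes with equal copies merge into one segment covering the
    hull of their clones.  Copy number must not increase distally unless an
    internal deletion was flagged — isodicentric markers may step down
    (2 -> 1 -> 0) across asymmetric breakpoints, but a 0 -> 1 rise without a
    deletion means conflicting calls.
    """
    if not calls:
        return []
    flags = flags or []
    ordered = _ordered(calls)
    arm = ordered[0].arm

    # conflict check on integer copies
    prev_int: int | None = None
    for c in ordered:
        cp = _COPIES[c.signal]
        if isinstance(cp, int):
            if prev_int is not None and cp > prev_int and INTERNAL_DELETION not in flags:
                raise DosageConflictError(
                    f"copy number rises distally at probe {c.probe.name} "
                    f"({prev_int} -> {cp}) without an internal deletion"
                )
            prev_int = cp

    segments: list[SegmentDosage] = []
    run: list[ProbeCall] = []

    def flush() -> None:
        if not run:
            return
        cp = _COPIES[run[0].signal]
        positions = [p for c in run for p in (c.probe.primary.start, c.probe.primary.end)]
        region = GenomicInterval(arm.chrom, min(positions), max(positions))
        segments.append(SegmentDosage(region, cp, SegmentDosage.label_for(cp)))

    for c in ordered:
        if run and _COPIES[c.signal] != _COPIES[run[0].signal]:
            flush()
            run = []
        run.append(c)
    flush()
    return segments


# --------------------------------------------------------------------------
# Content sizing

def size_content(
    arm_results: list[ArmBreakpointResult],
    junctions: dict[str, Junction],
    marker_class: str,
) -> tuple[float, float]:
    """Bound the euchromatic DNA content in Mb, summed over arms.

    Per arm the minimum is the junction-to-nearest-breakpoint-bound
    distance (clamped at zero) and the maximum the distance to the farthest
    bound, +inf when the breakpoint is open-ended distally.  A marker
    classified heterochromatic-only carries no euchromatin: (0, 0).
    """
    if marker_class == HETEROCHROMATIC_ONLY:
        return 0.0, 0.0
    total_min = 0.0
    total_max = 0.0
    for res in arm_results:
        junction = junctions.get(res.arm.name)
        ref = (
            junction.position
            if junction is not None and junction.defined
            else res.arm.proximal_pos
        )
        # the outermost (most distal) interval bounds the content on this arm
        best = max(
            res.intervals,
            key=lambda bi: max(
                arm_distance(res.arm, ref, bi.region.start),
                arm_distance(res.arm, ref, bi.region.end),
            ),
        )
        d1 = arm_distance(res.arm, ref, best.region.start)
        d2 = arm_distance(res.arm, ref, best.region.end)
        lo, hi = sorted((d1, d2))
        total_min += max(0.0, lo) / 1e6
        total_max = (
            math.inf
            if best.open_distal or math.isinf(total_max)
            else total_max + max(0.0, hi) / 1e6
        )
    return total_min, total_max


# --------------------------------------------------------------------------
# Mosaicism

def mosaic_fraction(
    n_with_marker: int, n_total: int, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Marker mosaic fraction with a two-sided Clopper-Pearson exact CI."""
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if not (0 <= n_with_marker <= n_total):
        raise ValueError("n_with_marker outside [0, n_total]")
    k, n = n_with_marker, n_total
    frac = k / n
    lower = 0.0 if k == 0 else float(_beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(_beta.ppf(1 - alpha / 2, k + 1, n - k))
    return frac, (lower, upper)


def required_metaphases(
    mosaic_level: float,
    confidence: float = 0.95,
    floor: int | None = 16,
) -> int:
    """Smallest metaphase count detecting a mosaic marker at a confidence.

    Solves 1 - (1-m)^n >= c, i.e. n = ceil(ln(1-c)/ln(1-m)).  The result is
    never below the configured floor (16 metaphases by default, the usual
    non-mosaic workup) unless ``floor`` is None.
    """
    if not (0 < mosaic_level <= 1):
        raise ValueError("mosaic level must lie in (0, 1]")
    if not (0 < confidence < 1):
        raise ValueError("confidence must lie in (0, 1)")
    if mosaic_level == 1.0:
        n = 1
    else:
        raw = math.log(1 - confidence) / math.log(1 - mosaic_level)
        n = math.ceil(round(raw, 12))
    return n if floor is None else max(n, floor)


# --------------------------------------------------------------------------
# End-to-end characterization of one observation

def characterize(
    obs: MarkerObservation, junctions: dict[str, Junction]
) -> MarkerCharacterization:
    """Run the full FISH-only inference chain on one marker observation."""
    marker_class = classify_marker(obs)
    chz = MarkerCharacterization(obs.case_id, marker_class)
    if marker_class == UNDETERMINED:
        chz.flags.append("no_calls")
        return chz

    arm_results: list[ArmBreakpointResult] = []
    for arm_name, calls in sorted(obs.calls_by_arm().items()):
        res = infer_breakpoint(calls, junctions.get(arm_name))
        arm_results.append(res)
        chz.breakpoints.extend(res.intervals)
        for f in res.flags:
            if f not in chz.flags:
                chz.flags.append(f)
        try:
            chz.segments.extend(
                infer_dosage(calls, obs.structure, flags=res.flags)
            )
        except DosageConflictError:
            chz.flags.append("cross_hybridization_conflict")

    if marker_class == EUCHROMATIC:
        euchromatic_arms = [
            r
            for r in arm_results
            if any(
                c.signal != ABSENT
                for c in obs.calls
                if c.arm.name == r.arm.name
            )
        ]
        chz.content_min_mb, chz.content_max_mb = size_content(
            euchromatic_arms, junctions, marker_class
        )
    if obs.n_metaphases_total > 0:
        chz.mosaic_fraction, chz.mosaic_ci = mosaic_fraction(
            obs.n_metaphases_with_marker, obs.n_metaphases_total
        )
    return chz
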