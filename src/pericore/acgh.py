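"""Array-CGH segment handling and FISH breakpoint refinement.

Array CGH segments (e.g. ADM-2 output) are consumed, not computed.  Each
gain segment carries optional boundary-uncertainty intervals — the span
between the last normal and first gained oligonucleotide probe at each
edge — which intersect the wider FISH-derived breakpoint interval to
produce a refined one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genome import ChromosomeArm, GenomicInterval, intersect
from .markers import ACGH_REFINED, BreakpointInterval

__all__ = [
    "AcghSegment",
    "AssayConflictError",
    "load_segments",
    "refine_breakpoint",
    "acgh_only_breakpoint",
    "GAIN",
    "LOSS",
    "NORMAL",
]

GAIN = "gain"
LOSS = "loss"
NORMAL = "normal"

#: Default |log2 ratio| at or above which a segment is called gained/lost.
DEFAULT_LOG2_THRESHOLD = 0.3


class AssayConflictError(ValueError):
    """FISH and array-CGH breakpoint intervals are disjoint."""

    def __init__(self, fish: GenomicInterval, acgh: GenomicInterval):
        super().__init__(
            f"FISH interval {fish} and aCGH boundary interval {acgh} are disjoint"
        )
        self.fish = fish
        self.acgh = acgh


@dataclass(frozen=True)
class AcghSegment:
    region: GenomicInterval
    mean_log2: float
    call: str  # gain | loss | normal
    #: Probe-to-probe uncertainty interval at the segment's start edge
    #: (last normal probe .. first aberrant probe), if supplied.
    start_uncertainty: GenomicInterval | None = None
    end_uncertainty: GenomicInterval | None = None

    def boundary_intervals(self) -> list[GenomicInterval]:
        """Boundary-uncertainty intervals at both edges.

        Falls back to zero-width intervals at the segment edges when no
        probe pair was supplied.
        """
        start = self.start_uncertainty or GenomicInterval(
            self.region.chrom, self.region.start, self.region.start
        )
        end = self.end_uncertainty or GenomicInterval(
            self.region.chrom, self.region.end, self.region.end
        )
        return [start, end]


def call_for(mean_log2: float, threshold: float = DEFAULT_LOG2_THRESHOLD) -> str:
    if mean_log2 >= threshold:
        return GAIN
    if mean_log2 <= -threshold:
        return LOSS
    return NORMAL


def load_segments(
    path: str | Path, threshold: float = DEFAULT_LOG2_THRESHOLD
) -> tuple[list[AcghSegment], list[str]]:
    """Load an aCGH segment TSV (chrom, start, end, mean_log2 [+ edge pairs]).

    Optional columns ``start_lo, start_hi, end_lo, end_hi`` carry the
    boundary-uncertainty probe pairs.  Returns the sorted segments and a
    list of warnings (e.g. overlapping gain segments on one chromosome).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "mean_log2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    segments: list[AcghSegment] = []
    for _, row in df.iterrows():
        region = GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]))
        log2 = float(row["mean_log2"])

        def _edge(lo_col: str, hi_col: str) -> GenomicInterval | None:
            if lo_col in df.columns and hi_col in df.columns and pd.notna(row[lo_col]):
                return GenomicInterval(region.chrom, int(row[lo_col]), int(row[hi_col]))
            return None

        segments.append(
            AcghSegment(
                region,
                log2,
                call_for(log2, threshold),
                start_uncertainty=_edge("start_lo", "start_hi"),
                end_uncertainty=_edge("end_lo", "end_hi"),
            )
        )
    segments.sort(key=lambda s: (s.region.chrom, s.region.start, s.region.end))

    warnings: list[str] = []
    gains = [s for s in segments if s.call == GAIN]
    for a, b in zip(gains, gains[1:]):
        if a.region.overlaps(b.region):
            warnings.append(
                f"overlapping gain segments on {a.region.chrom}: {a.region} / {b.region}"
            )
    return segments, warnings


def refine_breakpoint(
    fish: BreakpointInterval,
    segments: list[AcghSegment] | GenomicInterval,
) -> BreakpointInterval:
    """Narrow a FISH breakpoint interval with an aCGH boundary interval.

    The refinement is the intersection of the FISH interval with the gain
    segment's boundary-uncertainty interval on the same chromosome.  A
    boundary interval may also be supplied explicitly.  Disjoint intervals
    raise :class:`AssayConflictError` — the two assays disagree.
    """
    if isinstance(segments, GenomicInterval):
        candidates = [segments]
    else:
        candidates = [
            b
            for s in segments
            if s.call == GAIN and s.region.chrom == fish.region.chrom
            for b in s.boundary_intervals()
        ]
    if not candidates:
        raise ValueError(
            f"no gain segment on {fish.region.chrom} to refine against"
        )
    best: GenomicInterval | None = None
    nearest: GenomicInterval | None = None
    for b in candidates:
        if b.chrom != fish.region.chrom:
            continue
        nearest = nearest or b
        hit = intersect(fish.region, b)
        if hit is not None and (best is None or hit.width > best.width):
            best = hit
    if best is None:
        raise AssayConflictError(fish.region, nearest)
    return BreakpointInterval(fish.arm, best, ACGH_REFINED)


def acgh_only_breakpoint(
    segments: list[AcghSegment], arm: ChromosomeArm
) -> BreakpointInterval | None:
    """Breakpoint bounded solely by aCGH at a gain segment's distal edge.

    Used when the arm's FISH probes are uninformative (e.g. all proximal of
    the imbalance).  Returns None when no gain segment lies on the arm.
    """
    gains = [
        s
        for s in segments
        if s.call == GAIN
        and s.region.chrom == arm.chrom
        and s.region.overlaps(arm.extent)
    ]
    if not gains:
        return None
    # the gain reaching farthest toward the telomere bounds the content
    if arm.arm == "q":
        seg = max(gains, key=lambda s: s.region.end)
        boundary = seg.end_uncertainty or GenomicInterval(
            seg.region.chrom, seg.region.end, seg.region.end
        )
    else:
        seg = min(gains, key=lambda s: s.region.start)
        boundary = seg.start_uncertainty or GenomicInterval(
            seg.region.chrom, seg.region.start, seg.region.start
        )
    return BreakpointInterval(arm, boundary, ACGH_REFINED)
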