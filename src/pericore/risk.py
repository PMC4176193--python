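"""Phenotype-risk classification against critical/noncritical region maps.

Pericentromeric euchromatin splits, per arm, into a *noncritical* region
adjacent to the centromere (extra dosage tolerated), a *critical* region
farther out (extra dosage associated with abnormal phenotypes), and
possibly a gap of unknown status between them.  Region boundaries are
user-supplied annotation (e.g. from the sSMC literature), never shipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome import GenomicInterval
from .markers import (
    HETEROCHROMATIC_ONLY,
    MarkerCharacterization,
    SegmentDosage,
)

__all__ = [
    "ArmRegions",
    "CriticalRegionMap",
    "RiskAssessment",
    "load_critical_map",
    "classify_risk",
    "LIKELY_BENIGN",
    "LIKELY_PATHOGENIC",
    "UNCERTAIN",
]

LIKELY_BENIGN = "likely_benign"
LIKELY_PATHOGENIC = "likely_pathogenic"
UNCERTAIN = "uncertain"

OVERLAP_CRITICAL = "critical"
OVERLAP_NONCRITICAL = "noncritical"
OVERLAP_GAP = "gap"
OVERLAP_UNKNOWN = "unknown"


@dataclass(frozen=True)
class ArmRegions:
    """Critical/noncritical annotation for one chromosome arm."""

    arm: str  # e.g. "4p"
    noncritical: GenomicInterval | None
    critical_start: int | None  # boundary bp; critical region lies distal of it
    gap: GenomicInterval | None = None
    provenance: str = ""

    @property
    def chrom(self) -> str:
        return "chr" + self.arm[:-1]

    @property
    def side(self) -> str:
        return self.arm[-1]

    def overlap_class(self, region: GenomicInterval) -> str:
        """Classify a dosage segment against this arm's annotation."""
        if region.chrom != self.chrom:
            return OVERLAP_UNKNOWN
        if self.critical_start is not None:
            # critical region extends distally from the boundary
            if self.side == "q" and region.end > self.critical_start:
                return OVERLAP_CRITICAL
            if self.side == "p" and region.start < self.critical_start:
                return OVERLAP_CRITICAL
        if self.noncritical is not None and self.noncritical.contains(region):
            return OVERLAP_NONCRITICAL
        if self.gap is not None and self.gap.overlaps(region):
            return OVERLAP_GAP
        if self.critical_start is None:
            return OVERLAP_UNKNOWN
        return OVERLAP_GAP


@dataclass
class CriticalRegionMap:
    regions: dict[str, ArmRegions] = field(default_factory=dict)

    def for_arm(self, arm: str) -> ArmRegions | None:
        return self.regions.get(arm)

    def for_region(self, region: GenomicInterval) -> list[ArmRegions]:
        return [r for r in self.regions.values() if r.chrom == region.chrom]


def load_critical_map(path: str | Path) -> CriticalRegionMap:
    """Read a critical-region TSV.

    Columns: arm, noncritical_start, noncritical_end, critical_start,
    gap_start, gap_end, provenance.  Empty cells mean unknown.
    """
    df = pd.read_csv(path, sep="\t", dtype={"arm": str})
    out = CriticalRegionMap()
    for _, row in df.iterrows():
        arm = str(row["arm"])
        chrom = "chr" + arm[:-1]

        def _iv(a: str, b: str) -> GenomicInterval | None:
            if a in df.columns and pd.notna(row[a]) and pd.notna(row[b]):
                return GenomicInterval(chrom, int(row[a]), int(row[b]))
            return None

        critical_start = (
            int(row["critical_start"])
            if "critical_start" in df.columns and pd.notna(row["critical_start"])
            else None
        )
        out.regions[arm] = ArmRegions(
            arm=arm,
            noncritical=_iv("noncritical_start", "noncritical_end"),
            critical_start=critical_start,
            gap=_iv("gap_start", "gap_end"),
            provenance=str(row["provenance"]) if "provenance" in df.columns and pd.notna(row.get("provenance")) else "",
        )
    return out


@dataclass
class RiskAssessment:
    label: str
    drivers: list[tuple[SegmentDosage, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def classify_risk(
    chz: MarkerCharacterization,
    region_map: CriticalRegionMap,
    mosaic_attenuation_threshold: float = 0.30,
) -> RiskAssessment:
    """Label a characterized marker likely benign / pathogenic / uncertain.

    Heterochromatic-only markers, and euchromatic markers whose dosage
    segments all lie within annotated noncritical regions, are likely
    benign.  Any segment with at least one marker copy overlapping a
    critical region is likely pathogenic.  Unknown arm boundaries or
    segments confined to the gap between the regions yield *uncertain*.
    Low-level mosaicism adds an attenuation note but never changes the
    label.
    """
    if chz.marker_class not in (HETEROCHROMATIC_ONLY, "euchromatic"):
        raise ValueError(f"cannot assess risk for class {chz.marker_class!r}")

    assessment = RiskAssessment(LIKELY_BENIGN)
    if chz.marker_class == HETEROCHROMATIC_ONLY:
        assessment.notes.append("marker carries heterochromatin only")
    else:
        any_critical = False
        any_uncertain = False
        dosed = [
            s
            for s in chz.segments
            if s.marker_copies == "partial"
            or (isinstance(s.marker_copies, int) and s.marker_copies >= 1)
        ]
        if not dosed:
            raise ValueError("euchromatic marker without dosage segments")
        for seg in dosed:
            candidates = region_map.for_region(seg.region)
            if not candidates:
                assessment.drivers.append((seg, OVERLAP_UNKNOWN))
                any_uncertain = True
                continue
            classes = {r.overlap_class(seg.region) for r in candidates}
            if OVERLAP_CRITICAL in classes:
                cls = OVERLAP_CRITICAL
                any_critical = True
            elif OVERLAP_NONCRITICAL in classes:
                cls = OVERLAP_NONCRITICAL
            elif OVERLAP_GAP in classes:
                cls = OVERLAP_GAP
                any_uncertain = True
            else:
                cls = OVERLAP_UNKNOWN
                any_uncertain = True
            assessment.drivers.append((seg, cls))
        if any_critical:
            assessment.label = LIKELY_PATHOGENIC
        elif any_uncertain:
            assessment.label = UNCERTAIN

    if (
        chz.mosaic_fraction is not None
        and chz.mosaic_fraction < mosaic_attenuation_threshold
    ):
        assessment.notes.append(
            f"low-level mosaicism ({chz.mosaic_fraction:.0%}) may attenuate "
            "the phenotypic effect"
        )
    return assessment
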