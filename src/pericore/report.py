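"""Case reports, JSON (de)serialization, and the end-to-end pipeline.

The pipeline encodes the two-stage diagnostic workflow: the most proximal
core probes first discriminate euchromatic from heterochromatic markers,
then fine breakpoint mapping proceeds with probes within and distal to the
core, optionally refined by array-CGH segment boundaries, and finally the
dosage segments are mapped onto critical/noncritical region annotation.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .acgh import AcghSegment, refine_breakpoint
from .genome import (
    Assembly,
    ChromosomeArm,
    CloneRecord,
    GenomicInterval,
    format_region,
    intersect,
)
from .markers import (
    ACGH_REFINED,
    ArmBreakpointResult,
    BreakpointInterval,
    EUCHROMATIC,
    HETEROCHROMATIC_ONLY,
    MarkerCharacterization,
    MarkerObservation,
    ProbeCall,
    characterize,
    size_content,
)
from .panels import CorePanel, Junction, panel_stats
from .risk import CriticalRegionMap, classify_risk

__all__ = [
    "CaseReport",
    "run_pipeline",
    "render_text",
    "validate_report",
    "write_panels_json",
    "load_panels_json",
    "write_panels_tsv",
    "load_calls_tsv",
]


# --------------------------------------------------------------------------
# panels.json round-trip

def _arm_to_dict(arm: ChromosomeArm) -> dict:
    return {
        "chrom": arm.chrom,
        "arm": arm.arm,
        "start": arm.extent.start,
        "end": arm.extent.end,
        "acrocentric_p": arm.acrocentric_p,
    }


def _arm_from_dict(d: dict) -> ChromosomeArm:
    return ChromosomeArm(
        d["chrom"],
        d["arm"],
        GenomicInterval(d["chrom"], d["start"], d["end"]),
        acrocentric_p=d.get("acrocentric_p", False),
    )


def write_panels_json(
    path: str | Path,
    assembly: Assembly,
    junctions: dict[str, Junction],
    panels: dict[str, CorePanel],
) -> None:
    doc = {
        "assembly": {
            "label": assembly.label,
            "chrom_lengths": dict(assembly.chrom_lengths),
        },
        "arms": {
            name: _arm_to_dict(j.arm) for name, j in junctions.items()
        },
        "junctions": {
            name: {"position": j.position, "status": j.status}
            for name, j in junctions.items()
        },
        "panels": {
            name: {
                "status": p.status,
                "status_note": p.status_note,
                "junction": p.junction,
                "clones": [
                    {
                        "name": c.name,
                        "chrom": c.primary.chrom,
                        "start": c.primary.start,
                        "end": c.primary.end,
                    }
                    for c in p.clones
                ],
            }
            for name, p in panels.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_panels_json(
    path: str | Path,
) -> tuple[Assembly, dict[str, Junction], dict[str, CorePanel]]:
    doc = json.loads(Path(path).read_text())
    assembly = Assembly(doc["assembly"]["label"], doc["assembly"]["chrom_lengths"])
    arms = {name: _arm_from_dict(d) for name, d in doc["arms"].items()}
    junctions = {
        name: Junction(arms[name], j["position"], j["status"])
        for name, j in doc["junctions"].items()
    }
    panels = {}
    for name, p in doc["panels"].items():
        clones = [
            CloneRecord(c["name"], GenomicInterval(c["chrom"], c["start"], c["end"]))
            for c in p["clones"]
        ]
        panels[name] = CorePanel(
            arms[name], p["junction"], clones, p["status"], p["status_note"]
        )
    return assembly, junctions, panels


def write_panels_tsv(path: str | Path, panels: dict[str, CorePanel]) -> None:
    """A per-arm table mirroring the published bookkeeping columns."""
    rows = []
    for name in sorted(panels):
        p = panels[name]
        st = panel_stats(p)
        rows.append(
            {
                "arm": name,
                "junction": p.junction,
                "proximal_clone": p.proximal_clone.name if p.proximal_clone else "",
                "d_het_prox_mb": st.d_het_prox,
                "distal_clone": p.distal_clone.name if p.distal_clone else "",
                "core_span_mb": st.core_span,
                "status": p.status,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Probe-call TSV

def load_calls_tsv(
    path: str | Path, arms: dict[str, ChromosomeArm]
) -> list[MarkerObservation]:
    """Read per-probe FISH calls grouped into one observation per case."""
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str, "arm": str})
    required = {
        "case_id", "probe_name", "chrom", "start", "end", "arm", "signal",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    observations = []
    for case_id, grp in df.groupby("case_id", sort=True):
        calls = []
        for _, row in grp.iterrows():
            arm_name = str(row["arm"])
            if arm_name not in arms:
                raise ValueError(f"{path}: unknown arm {arm_name!r}")
            clone = CloneRecord(
                str(row["probe_name"]),
                GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"])),
            )
            calls.append(ProbeCall(clone, arms[arm_name], str(row["signal"])))
        first = grp.iloc[0]
        observations.append(
            MarkerObservation(
                case_id=str(case_id),
                structure=str(first["structure_hint"])
                if "structure_hint" in grp.columns
                else "unknown",
                calls=calls,
                n_metaphases_total=int(first.get("n_metaphases_total", 0)),
                n_metaphases_with_marker=int(first.get("n_metaphases_with_marker", 0)),
            )
        )
    return observations


# --------------------------------------------------------------------------
# CaseReport

def _bi_to_dict(bi: BreakpointInterval) -> dict:
    return {
        "arm": bi.arm.name,
        "region": format_region(bi.region),
        "basis": bi.basis,
        "open_distal": bi.open_distal,
    }


@dataclass
class CaseReport:
    case_id: str
    structure: str
    marker_class: str
    breakpoints: list[dict] = field(default_factory=list)
    segments: list[dict] = field(default_factory=list)
    content_min_mb: float = 0.0
    content_max_mb: float | None = 0.0  # None encodes an open-ended bound
    mosaic_fraction: float | None = None
    mosaic_ci: list[float] | None = None
    flags: list[str] = field(default_factory=list)
    refinements: list[dict] = field(default_factory=list)
    risk: dict | None = None
    tool_version: str = __version__
    input_digests: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "structure": self.structure,
            "marker_class": self.marker_class,
            "breakpoints": self.breakpoints,
            "segments": self.segments,
            "content_min_mb": self.content_min_mb,
            "content_max_mb": self.content_max_mb,
            "mosaic_fraction": self.mosaic_fraction,
            "mosaic_ci": self.mosaic_ci,
            "flags": self.flags,
            "refinements": self.refinements,
            "risk": self.risk,
            "tool_version": self.tool_version,
            "input_digests": self.input_digests,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_dict(cls, d: dict) -> "CaseReport":
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "CaseReport":
        return cls.from_dict(json.loads(text))


def _schema() -> dict:
    with resources.files("pericore").joinpath("case_report.schema.json").open() as fh:
        return json.load(fh)


def validate_report(doc: dict) -> list[str]:
    """Structural validation of a report dict against the shipped schema.

    Checks required keys and primitive types; returns a list of problems
    (empty when the document conforms).
    """
    schema = _schema()
    problems: list[str] = []
    type_map = {
        "string": str,
        "number": (int, float),
        "integer": int,
        "array": list,
        "object": dict,
        "boolean": bool,
        "null": type(None),
    }
    props = schema["properties"]
    for key in schema.get("required", []):
        if key not in doc:
            problems.append(f"missing required key {key!r}")
    for key, value in doc.items():
        if key not in props:
            problems.append(f"unexpected key {key!r}")
            continue
        allowed = props[key]["type"]
        if isinstance(allowed, str):
            allowed = [allowed]
        ok = any(
            isinstance(value, type_map[t])
            and not (t == "integer" and isinstance(value, bool))
            for t in allowed
        )
        if not ok:
            problems.append(f"key {key!r} has type {type(value).__name__}, expected {allowed}")
    return problems


# --------------------------------------------------------------------------
# Pipeline

def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _characterization_to_report(
    chz: MarkerCharacterization, obs: MarkerObservation
) -> CaseReport:
    return CaseReport(
        case_id=chz.case_id,
        structure=obs.structure,
        marker_class=chz.marker_class,
        breakpoints=[_bi_to_dict(b) for b in chz.breakpoints],
        segments=[
            {
                "region": format_region(s.region),
                "marker_copies": s.marker_copies,
                "total_dosage": s.total_dosage,
            }
            for s in chz.segments
        ],
        content_min_mb=round(chz.content_min_mb, 2),
        content_max_mb=(
            None if math.isinf(chz.content_max_mb) else round(chz.content_max_mb, 2)
        ),
        mosaic_fraction=chz.mosaic_fraction,
        mosaic_ci=list(chz.mosaic_ci) if chz.mosaic_ci else None,
        flags=list(chz.flags),
    )


def run_pipeline(
    observations: list[MarkerObservation],
    junctions: dict[str, Junction],
    arms: dict[str, ChromosomeArm],
    acgh_segments: list[AcghSegment] | None = None,
    critical_map: CriticalRegionMap | None = None,
    input_digests: dict | None = None,
) -> list[CaseReport]:
    """Characterize every case: classify, map breakpoints, dose, size,
    estimate mosaicism, refine with aCGH when supplied, and assess risk.

    Assay conflicts between FISH and aCGH become report flags, not errors.
    """
    reports: list[CaseReport] = []
    for obs in observations:
        chz = characterize(obs, junctions)

        refinements: list[dict] = []
        if acgh_segments and chz.marker_class == EUCHROMATIC:
            refined: list[BreakpointInterval] = []
            for bi in chz.breakpoints:
                gains_here = [
                    s
                    for s in acgh_segments
                    if s.call == "gain"
                    and s.region.chrom == bi.region.chrom
                    and s.region.overlaps(bi.arm.extent)
                ]
                if bi.basis == ACGH_REFINED or not gains_here:
                    refined.append(bi)
                    continue
                boundary_hit = any(
                    intersect(bi.region, b) is not None
                    for s in gains_here
                    for b in s.boundary_intervals()
                )
                if not boundary_hit:
                    # inside a gain body there is nothing to refine; an
                    # interval nowhere near the arm's gain means the two
                    # assays disagree
                    if not any(s.region.overlaps(bi.region) for s in gains_here):
                        if "assay_conflict" not in chz.flags:
                            chz.flags.append("assay_conflict")
                    refined.append(bi)
                    continue
                new = refine_breakpoint(bi, gains_here)
                refinements.append(
                    {
                        "arm": bi.arm.name,
                        "fish": format_region(bi.region),
                        "refined": format_region(new.region),
                    }
                )
                refined.append(new)
            chz.breakpoints = refined
            # recompute the content bounds from the refined intervals
            by_arm: dict[str, list[BreakpointInterval]] = {}
            for bi in chz.breakpoints:
                by_arm.setdefault(bi.arm.name, []).append(bi)
            arm_results = [
                ArmBreakpointResult(ivs[0].arm, ivs) for ivs in by_arm.values()
            ]
            chz.content_min_mb, chz.content_max_mb = size_content(
                arm_results, junctions, chz.marker_class
            )

        report = _characterization_to_report(chz, obs)
        report.refinements = refinements
        report.input_digests = dict(input_digests or {})

        if critical_map is not None and chz.marker_class in (
            HETEROCHROMATIC_ONLY,
            EUCHROMATIC,
        ):
            assessment = classify_risk(chz, critical_map)
            report.risk = {
                "label": assessment.label,
                "drivers": [
                    {"region": format_region(s.region), "overlap": cls}
                    for s, cls in assessment.drivers
                ],
                "notes": assessment.notes,
            }
        reports.append(report)
    return reports


# --------------------------------------------------------------------------
# Text rendering

def _content_str(report: CaseReport) -> str:
    if report.marker_class == HETEROCHROMATIC_ONLY:
        return "0 Mb (heterochromatic only)"
    if report.content_max_mb is None:
        return f"> {report.content_min_mb:.2f} Mb"
    return f"{report.content_min_mb:.2f}–{report.content_max_mb:.2f} Mb"


def render_text(report: CaseReport) -> str:
    """Human-readable one-case summary in the field's coordinate style."""
    lines = [
        f"Case {report.case_id} ({report.structure})",
        f"  class: {report.marker_class.replace('_', ' ')}",
    ]
    if report.marker_class == HETEROCHROMATIC_ONLY:
        lines.append("  heterochromatic only; no euchromatic content detected")
    for bp in report.breakpoints:
        suffix = " (open distal)" if bp["open_distal"] else ""
        lines.append(
            f"  breakpoint {bp['arm']}: {bp['region']} [{bp['basis']}]{suffix}"
        )
    for seg in report.segments:
        lines.append(
            f"  dosage {seg['region']}: marker copies {seg['marker_copies']}"
            f" -> {seg['total_dosage']}"
        )
    lines.append(f"  euchromatic content: {_content_str(report)}")
    if report.mosaic_fraction is not None:
        lo, hi = report.mosaic_ci
        lines.append(
            f"  mosaic fraction: {report.mosaic_fraction:.2f}"
            f" (95% CI {lo:.2f}–{hi:.2f})"
        )
    if report.flags:
        lines.append(f"  flags: {', '.join(report.flags)}")
    if report.risk is not None:
        lines.append(f"  risk: {report.risk['label']}")
        for note in report.risk["notes"]:
            lines.append(f"    note: {note}")
    return "\n".join(lines) + "\n"
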