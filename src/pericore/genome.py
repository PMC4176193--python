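"""Coordinate conventions, interval algebra, and annotation-track readers.

Everything downstream (panel design, marker characterization, array-CGH
refinement) operates on the types defined here.  Intervals are stored
0-based half-open; locus strings in the ``chrN:A-B`` style used in the
cytogenetics literature are converted on input and output so that a
reported width is always the difference of the printed bounds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "Assembly",
    "GenomicInterval",
    "ChromosomeArm",
    "HeterochromatinBlock",
    "CloneRecord",
    "Tracks",
    "RegionParseError",
    "TrackLoadError",
    "parse_region_string",
    "format_region",
    "intersect",
    "width_mb",
    "width_kb",
    "arm_distance",
    "read_tracks",
    "HUMAN_ACROCENTRIC_P",
]

#: Human chromosomes whose short arm carries only satellite material.
HUMAN_ACROCENTRIC_P = frozenset({"chr13", "chr14", "chr15", "chr21", "chr22"})


class RegionParseError(ValueError):
    """A locus string could not be interpreted."""


class TrackLoadError(ValueError):
    """An annotation file violates its format or an invariant."""


@dataclass(frozen=True)
class Assembly:
    """A fixed reference assembly: a label and chromosome lengths in bp."""

    label: str
    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r} in assembly {self.label!r}") from None


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start > self.end:
            raise ValueError(
                f"start {self.start} exceeds end {self.end} on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def is_empty(self) -> bool:
        return self.start == self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return format_region(self)


@dataclass(frozen=True)
class ChromosomeArm:
    """One arm of a chromosome with its orientation convention.

    ``distal_direction`` is -1 on p arms (the telomere lies at smaller
    coordinates) and +1 on q arms.
    """

    chrom: str
    arm: str  # "p" or "q"
    extent: GenomicInterval
    acrocentric_p: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.extent.chrom != self.chrom:
            raise ValueError("arm extent lies on a different chromosome")
        if self.acrocentric_p and self.arm != "p":
            raise ValueError("only p arms can be acrocentric")

    @property
    def name(self) -> str:
        return f"{self.chrom.removeprefix('chr')}{self.arm}"

    @property
    def distal_direction(self) -> int:
        return -1 if self.arm == "p" else +1

    @property
    def proximal_pos(self) -> int:
        """The centromeric boundary of the arm."""
        return self.extent.end if self.arm == "p" else self.extent.start

    @property
    def distal_pos(self) -> int:
        """The telomeric boundary of the arm."""
        return self.extent.start if self.arm == "p" else self.extent.end


@dataclass(frozen=True)
class HeterochromatinBlock:
    region: GenomicInterval
    arm_side: str  # "p" or "q"

    def __post_init__(self) -> None:
        if self.arm_side not in ("p", "q"):
            raise ValueError(f"arm_side must be 'p' or 'q', got {self.arm_side!r}")


@dataclass(frozen=True)
class CloneRecord:
    """A FISH probe: a named clone with a primary genomic placement.

    ``alternates`` hold additional placements (cross-hybridization sites);
    ``segdup_fraction`` is the fraction of the primary placement covered by
    segmental duplications.
    """

    name: str
    primary: GenomicInterval
    alternates: tuple[GenomicInterval, ...] = ()
    segdup_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.segdup_fraction <= 1.0):
            raise ValueError(
                f"clone {self.name}: segdup_fraction {self.segdup_fraction} outside [0, 1]"
            )

    def proximal_edge(self, arm: ChromosomeArm) -> int:
        """Coordinate of the clone edge nearest the centromere."""
        return self.primary.end if arm.arm == "p" else self.primary.start

    def distal_edge(self, arm: ChromosomeArm) -> int:
        """Coordinate of the clone edge nearest the telomere."""
        return self.primary.start if arm.arm == "p" else self.primary.end


# --------------------------------------------------------------------------
# Locus-string parsing and formatting

_DASHES = "‐‑‒–—−"  # hyphen variants, en/em dash, minus
_REGION_RE = re.compile(
    rf"^\s*([A-Za-z0-9_.]+)\s*:\s*([\d,\s]+?)\s*[-{_DASHES}]\s*([\d,\s]+?)\s*$"
)


def parse_region_string(text: str, assembly: Assembly | None = None) -> GenomicInterval:
    """Parse a ``chrN:A-B`` locus string into a :class:`GenomicInterval`.

    Commas and stray spaces inside the numbers are ignored, and any of the
    dash characters found in print (hyphen, en dash, minus sign, ...) may
    separate the bounds.  The printed coordinates are kept as-is, so the
    interval's width equals ``B - A``.
    """
    m = _REGION_RE.match(text)
    if not m:
        raise RegionParseError(f"malformed region string: {text!r}")
    chrom, a_txt, b_txt = m.groups()
    try:
        a = int(re.sub(r"[,\s]", "", a_txt))
        b = int(re.sub(r"[,\s]", "", b_txt))
    except ValueError:
        raise RegionParseError(f"non-numeric coordinate in {text!r}") from None
    if a > b:
        raise RegionParseError(f"start {a:,} exceeds end {b:,} in {text!r}")
    if assembly is not None:
        if chrom not in assembly.chrom_lengths:
            raise RegionParseError(f"unknown chromosome {chrom!r} in {text!r}")
        if b > assembly.length_of(chrom):
            raise RegionParseError(
                f"coordinate {b:,} beyond end of {chrom} in {text!r}"
            )
    return GenomicInterval(chrom, a, b)


def format_region(iv: GenomicInterval) -> str:
    """Render an interval in ``chrN:A-B`` style with thousands separators."""
    return f"{iv.chrom}:{iv.start:,}-{iv.end:,}"


# --------------------------------------------------------------------------
# Interval arithmetic

#: Sentinel returned by :func:`intersect` for disjoint inputs.
EMPTY = None


def intersect(a: GenomicInterval, b: GenomicInterval) -> GenomicInterval | None:
    """Intersect two intervals on the same chromosome.

    Returns ``None`` when the intervals are disjoint.  Intervals that merely
    touch (``a.end == b.start``) intersect in a zero-width interval at the
    shared coordinate.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"cannot intersect {a.chrom} with {b.chrom}")
    start = max(a.start, b.start)
    end = min(a.end, b.end)
    if start > end:
        return None
    return GenomicInterval(a.chrom, start, end)


def _round_half_up(value: float | int, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(value).quantize(q, rounding=ROUND_HALF_UP))


def width_mb(iv: GenomicInterval, decimals: int = 1) -> float:
    """Interval width in megabases, rounded half-up to ``decimals``."""
    return _round_half_up(Decimal(iv.width) / Decimal(10**6), decimals)


def width_kb(iv: GenomicInterval, decimals: int = 0) -> float:
    """Interval width in kilobases, rounded half-up to ``decimals``."""
    return _round_half_up(Decimal(iv.width) / Decimal(10**3), decimals)


def arm_distance(arm: ChromosomeArm, from_pos: int, to_pos: int) -> int:
    """Signed distance along an arm; positive means toward the telomere."""
    return (to_pos - from_pos) * arm.distal_direction


# --------------------------------------------------------------------------
# Track readers

@dataclass
class Tracks:
    """Everything :func:`read_tracks` loads: assembly, arms, blocks, clones."""

    assembly: Assembly
    arms: dict[str, ChromosomeArm]  # keyed by arm name, e.g. "4p"
    het_blocks: list[HeterochromatinBlock]
    clones: list[CloneRecord]
    segdups: list[GenomicInterval] = field(default_factory=list)

    def arms_of(self, chrom: str) -> tuple[ChromosomeArm, ChromosomeArm]:
        short = chrom.removeprefix("chr")
        return self.arms[f"{short}p"], self.arms[f"{short}q"]

    def het_blocks_for(self, arm: ChromosomeArm) -> list[HeterochromatinBlock]:
        return [
            b
            for b in self.het_blocks
            if b.region.chrom == arm.chrom and b.arm_side == arm.arm
        ]


def _read_tsv_rows(path: Path, min_cols: int, label: str):
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise TrackLoadError(
                    f"{label} {path}, line {lineno}: expected at least "
                    f"{min_cols} columns, got {len(cols)}"
                )
            rows.append((lineno, cols))
    return rows


def read_chrom_sizes(path: str | Path, label: str = "assembly") -> Assembly:
    """Read a two-column (name, length) chromosome-sizes table."""
    lengths: dict[str, int] = {}
    for lineno, cols in _read_tsv_rows(Path(path), 2, "chrom sizes"):
        name = cols[0]
        if name in lengths:
            raise TrackLoadError(f"chrom sizes {path}, line {lineno}: duplicate chromosome {name!r}")
        try:
            lengths[name] = int(cols[1])
        except ValueError:
            raise TrackLoadError(
                f"chrom sizes {path}, line {lineno}: non-integer length {cols[1]!r}"
            ) from None
        if lengths[name] <= 0:
            raise TrackLoadError(f"chrom sizes {path}, line {lineno}: non-positive length")
    return Assembly(label, lengths)


def _check_within(assembly: Assembly, iv: GenomicInterval, path, lineno: int) -> None:
    if iv.chrom not in assembly.chrom_lengths:
        raise TrackLoadError(f"{path}, line {lineno}: unknown chromosome {iv.chrom!r}")
    if iv.end > assembly.length_of(iv.chrom):
        raise TrackLoadError(
            f"{path}, line {lineno}: interval end {iv.end:,} beyond chromosome end"
        )


def read_bed3(path: str | Path, assembly: Assembly) -> list[GenomicInterval]:
    out = []
    for lineno, cols in _read_tsv_rows(Path(path), 3, "BED"):
        try:
            iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
        except ValueError as exc:
            raise TrackLoadError(f"{path}, line {lineno}: {exc}") from None
        _check_within(assembly, iv, path, lineno)
        out.append(iv)
    return out


def read_clones_bed(path: str | Path, assembly: Assembly) -> list[CloneRecord]:
    """Read a BED4+ clone library.

    Column 5 (optional) is a comma-separated list of alternate placements in
    ``chr:start-end`` form; column 6 (optional) is the segdup fraction.
    """
    clones: list[CloneRecord] = []
    seen: set[str] = set()
    for lineno, cols in _read_tsv_rows(Path(path), 4, "clones BED"):
        try:
            primary = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
        except ValueError as exc:
            raise TrackLoadError(f"{path}, line {lineno}: {exc}") from None
        _check_within(assembly, primary, path, lineno)
        name = cols[3]
        if name in seen:
            raise TrackLoadError(f"{path}, line {lineno}: duplicate clone name {name!r}")
        seen.add(name)
        alternates: tuple[GenomicInterval, ...] = ()
        if len(cols) >= 5 and cols[4] not in ("", "."):
            try:
                alternates = tuple(
                    parse_region_string(tok) for tok in cols[4].split(",") if tok
                )
            except RegionParseError as exc:
                raise TrackLoadError(f"{path}, line {lineno}: {exc}") from None
        segdup = 0.0
        if len(cols) >= 6 and cols[5] not in ("", "."):
            segdup = float(cols[5])
        try:
            clones.append(CloneRecord(name, primary, alternates, segdup))
        except ValueError as exc:
            raise TrackLoadError(f"{path}, line {lineno}: {exc}") from None
    return clones


def _validate_het_blocks(blocks: Sequence[GenomicInterval], path) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in blocks:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        prev = None
        for iv in ivs:
            if prev is not None and iv.start < prev.end:
                raise TrackLoadError(
                    f"{path}: heterochromatin blocks on {chrom} unsorted or overlapping "
                    f"near {iv.start:,}"
                )
            prev = iv


def derive_arms(
    assembly: Assembly,
    het_blocks: Sequence[GenomicInterval],
    acrocentric_p: frozenset[str] | set[str] = HUMAN_ACROCENTRIC_P,
) -> tuple[dict[str, ChromosomeArm], list[HeterochromatinBlock]]:
    """Split each chromosome into p and q arms around its heterochromatic root.

    The p/q boundary is taken as the midpoint of the chromosome's
    heterochromatin span (the midpoint of the chromosome when no block is
    annotated), and each block is assigned to the arm whose side of the
    boundary holds its centre.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in het_blocks:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    arms: dict[str, ChromosomeArm] = {}
    typed_blocks: list[HeterochromatinBlock] = []
    for chrom, length in assembly.chrom_lengths.items():
        blocks = sorted(by_chrom.get(chrom, []), key=lambda iv: iv.start)
        if blocks:
            mid = (blocks[0].start + blocks[-1].end) // 2
        else:
            mid = length // 2
        short = chrom.removeprefix("chr")
        arms[f"{short}p"] = ChromosomeArm(
            chrom, "p", GenomicInterval(chrom, 0, mid), acrocentric_p=chrom in acrocentric_p
        )
        arms[f"{short}q"] = ChromosomeArm(chrom, "q", GenomicInterval(chrom, mid, length))
        for iv in blocks:
            side = "p" if (iv.start + iv.end) // 2 < mid else "q"
            typed_blocks.append(HeterochromatinBlock(iv, side))
    return arms, typed_blocks


def read_tracks(
    chrom_sizes: str | Path,
    het_bed: str | Path,
    clones_bed: str | Path,
    segdup_bed: str | Path | None = None,
    *,
    label: str = "assembly",
    acrocentric_p: frozenset[str] | set[str] = HUMAN_ACROCENTRIC_P,
) -> Tracks:
    """Load all annotation tracks and derive the arm table."""
    assembly = read_chrom_sizes(chrom_sizes, label)
    het_raw = read_bed3(het_bed, assembly)
    _validate_het_blocks(het_raw, het_bed)
    clones = read_clones_bed(clones_bed, assembly)
    segdups = read_bed3(segdup_bed, assembly) if segdup_bed else []
    arms, blocks = derive_arms(assembly, het_raw, acrocentric_p)
    return Tracks(assembly, arms, blocks, clones, segdups)
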