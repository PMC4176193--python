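"""Seed-controlled toy genomes, clone libraries, and simulated marker cases.

The generator emulates the landscape the probe panels target: each
chromosome carries a heterochromatic block at the root of both arms, with
euchromatin beyond, and a BAC-like clone library (150-200 kb inserts) tiles
the proximal euchromatin of every non-acrocentric arm.  Simulated marker
chromosomes (rings, isodicentrics, minutes) come with full ground truth so
the inference chain can be validated end to end.

Observation model: a probe fully inside marker content produces a single
(one extra copy) or double (two extra copies, isodicentric) signal; partial
overlap produces a diminished signal; overlap below the FISH detectability
floor (10 kb) is called absent.  Array-CGH gain segments snap to a 43 kb
probe grid with the flanking probe pair as boundary uncertainty, and
metaphase counts are drawn binomially at the planted mosaic level.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .acgh import AcghSegment, call_for
from .genome import (
    Assembly,
    ChromosomeArm,
    CloneRecord,
    GenomicInterval,
    Tracks,
    arm_distance,
    derive_arms,
)
from .markers import (
    ABSENT,
    DIMINISHED,
    DOUBLE,
    SINGLE,
    MarkerObservation,
    ProbeCall,
)

__all__ = ["SimConfig", "SimTruth", "generate_genome", "simulate_case", "write_genome_files"]

#: FISH cannot resolve content below this overlap (bp); called absent.
DETECTABILITY_FLOOR_BP = 10_000
#: Overlap fraction at or above which a probe reports a full signal.
FULL_SIGNAL_FRACTION = 0.8
#: Oligonucleotide probe spacing used for simulated aCGH boundary pairs.
ACGH_PROBE_SPACING_BP = 43_000


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the toy-genome generator; same seed, same output."""

    n_chromosomes: int = 6
    n_acrocentric: int = 1
    chrom_length_range: tuple[int, int] = (60_000_000, 160_000_000)
    het_width_range: tuple[int, int] = (2_000_000, 8_000_000)
    clone_width_range: tuple[int, int] = (150_000, 200_000)
    tiling_overlap_range: tuple[int, int] = (10_000, 40_000)
    proximal_tile_bp: int = 1_500_000
    segdup_density: float = 0.10
    offtarget_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.chrom_length_range,
            self.het_width_range,
            self.clone_width_range,
            self.tiling_overlap_range,
        ):
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range ({lo}, {hi})")
        if self.n_acrocentric >= self.n_chromosomes:
            raise ValueError("need at least one non-acrocentric chromosome")
        w_lo = self.clone_width_range[0]
        if self.tiling_overlap_range[1] >= w_lo:
            raise ValueError("tiling overlap must be below the clone width")


@dataclass
class SimTruth:
    """Planted ground truth of one simulated marker case."""

    case_id: str
    structure: str
    chrom: str
    #: content-end breakpoint per arm name (None = no euchromatic content)
    arm_breakpoints: dict[str, int | None]
    #: euchromatic content regions with their marker copy number
    segments: list[tuple[str, int, int, int]]  # (chrom, start, end, copies)
    content_bp: int
    mosaic_level: float
    false_negative: float = 0.0
    false_positive: float = 0.0


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_genome(config: SimConfig = SimConfig()) -> Tracks:
    """Generate an arm-structured toy genome with a tiling clone library.

    Every non-acrocentric arm gets a het/eu junction and a clone tiling of
    its proximal euchromatin; decoy clones with off-target placements or
    heavy segdup coverage are sprinkled in for the specificity screen.
    """
    rng = _rng(config.seed)
    lengths: dict[str, int] = {}
    het_raw: list[GenomicInterval] = []
    acro: set[str] = set()

    for i in range(config.n_chromosomes):
        chrom = f"chr{i + 1}"
        length = int(rng.integers(*config.chrom_length_range, endpoint=True))
        lengths[chrom] = length
        cen = int(length * rng.uniform(0.35, 0.65))
        wp = int(rng.integers(*config.het_width_range, endpoint=True))
        wq = int(rng.integers(*config.het_width_range, endpoint=True))
        het_raw.append(GenomicInterval(chrom, cen - wp, cen))
        het_raw.append(GenomicInterval(chrom, cen, cen + wq))
        if i >= config.n_chromosomes - config.n_acrocentric:
            acro.add(chrom)

    assembly = Assembly(f"sim-seed{config.seed}", lengths)
    arms, blocks = derive_arms(assembly, het_raw, acrocentric_p=acro)

    clones: list[CloneRecord] = []
    segdups: list[GenomicInterval] = []
    chrom_names = list(lengths)

    for name, arm in arms.items():
        if arm.acrocentric_p:
            continue
        own = [b for b in blocks if b.region.chrom == arm.chrom and b.arm_side == arm.arm]
        junction = (
            min(b.region.start for b in own)
            if arm.arm == "p"
            else max(b.region.end for b in own)
        )
        # contiguous tiling of the proximal euchromatin, anchored at the junction
        frontier = junction
        k = 0
        while arm_distance(arm, junction, frontier) < config.proximal_tile_bp:
            w = int(rng.integers(*config.clone_width_range, endpoint=True))
            if arm.arm == "q":
                iv = GenomicInterval(arm.chrom, frontier, frontier + w)
            else:
                iv = GenomicInterval(arm.chrom, frontier - w, frontier)
            clones.append(CloneRecord(f"SIM-{name}-{k:02d}", iv))
            overlap = int(rng.integers(*config.tiling_overlap_range, endpoint=True))
            frontier = iv.end - overlap if arm.arm == "q" else iv.start + overlap
            k += 1
        # decoy clones for the specificity screen
        n_decoys = rng.binomial(k, config.segdup_density + config.offtarget_rate)
        for d in range(n_decoys):
            w = int(rng.integers(*config.clone_width_range, endpoint=True))
            off = int(rng.integers(0, config.proximal_tile_bp))
            if arm.arm == "q":
                start = junction + off
            else:
                start = max(0, junction - off - w)
            iv = GenomicInterval(arm.chrom, start, start + w)
            if rng.random() < config.offtarget_rate / (
                config.segdup_density + config.offtarget_rate
            ):
                other = chrom_names[int(rng.integers(0, len(chrom_names)))]
                alt = GenomicInterval(other, 1_000_000, 1_000_000 + w)
                clones.append(
                    CloneRecord(f"SIM-{name}-X{d:02d}", iv, alternates=(alt,))
                )
            else:
                frac = float(rng.uniform(0.6, 1.0))
                clones.append(
                    CloneRecord(f"SIM-{name}-S{d:02d}", iv, segdup_fraction=frac)
                )
                segdups.append(iv)

    return Tracks(assembly, arms, blocks, clones, segdups)


# --------------------------------------------------------------------------
# Case simulation

def _junction_of(tracks: Tracks, arm: ChromosomeArm) -> int:
    own = tracks.het_blocks_for(arm)
    if arm.arm == "p":
        return min(b.region.start for b in own)
    return max(b.region.end for b in own)


def _signal_for(
    clone: CloneRecord,
    regions: list[tuple[GenomicInterval, int]],
) -> str:
    """Deterministic observation model (noise applied by the caller)."""
    w = clone.primary.width
    o1 = sum(clone.primary.overlap_bp(r) for r, c in regions if c >= 1)
    o2 = sum(clone.primary.overlap_bp(r) for r, c in regions if c >= 2)
    if o1 < DETECTABILITY_FLOOR_BP:
        return ABSENT
    if o1 / w >= FULL_SIGNAL_FRACTION:
        return DOUBLE if o2 / w >= FULL_SIGNAL_FRACTION else SINGLE
    return DIMINISHED


def _acgh_segments_for(
    regions: list[tuple[GenomicInterval, int]],
    rng: np.random.Generator,
) -> list[AcghSegment]:
    """Gain segments snapped to the oligo grid with flanking probe pairs."""
    spacing = ACGH_PROBE_SPACING_BP
    phase = int(rng.integers(0, spacing))
    out: list[AcghSegment] = []
    for region, copies in regions:
        if copies < 1 or region.width < 2 * spacing:
            continue
        # first probe at or beyond the true start; last probe at or before the end
        det_start = phase + spacing * -((phase - region.start) // spacing)
        det_end = phase + spacing * ((region.end - phase) // spacing)
        if det_end <= det_start:
            continue
        log2 = 1.0 if copies >= 2 else 0.58
        out.append(
            AcghSegment(
                GenomicInterval(region.chrom, det_start, det_end),
                log2,
                call_for(log2),
                start_uncertainty=GenomicInterval(
                    region.chrom, max(0, det_start - spacing), det_start
                ),
                end_uncertainty=GenomicInterval(
                    region.chrom, det_end, det_end + spacing
                ),
            )
        )
    return out


def simulate_case(
    tracks: Tracks,
    panels: dict[str, "CorePanel"],
    seed: int,
    structure: str | None = None,
    het_only: bool = False,
    mosaic_level: float | None = None,
    false_negative: float = 0.0,
    false_positive: float = 0.0,
    case_id: str | None = None,
) -> tuple[MarkerObservation, list[AcghSegment], SimTruth]:
    """Simulate one marker-chromosome case against designed panels.

    Breakpoint placement keeps each planted copy-number region wide enough
    (>= ~0.4 Mb) that at least one probe falls fully inside it, except for
    *minute* markers, whose content may be sub-probe by design.
    """
    rng = _rng(seed)
    acro_chroms = {a.chrom for a in tracks.arms.values() if a.acrocentric_p}
    candidates = sorted(
        {a.chrom for a in tracks.arms.values() if a.chrom not in acro_chroms}
    )
    chrom = candidates[int(rng.integers(0, len(candidates)))]
    p_arm, q_arm = tracks.arms_of(chrom)
    if structure is None:
        structure = ["ring", "idic", "minute"][int(rng.integers(0, 3))]
    j_p = _junction_of(tracks, p_arm)
    j_q = _junction_of(tracks, q_arm)

    regions: list[tuple[GenomicInterval, int]] = []
    arm_breakpoints: dict[str, int | None] = {p_arm.name: None, q_arm.name: None}

    if het_only:
        # breakpoints inside the heterochromatic root: no euchromatin at all
        regions = []
    elif structure == "ring":
        d_p = int(rng.integers(400_000, 1_200_000))
        d_q = int(rng.integers(400_000, 1_200_000))
        regions = [
            (GenomicInterval(chrom, j_p - d_p, j_p), 1),
            (GenomicInterval(chrom, j_q, j_q + d_q), 1),
        ]
        arm_breakpoints[p_arm.name] = j_p - d_p
        arm_breakpoints[q_arm.name] = j_q + d_q
    elif structure == "minute":
        d_p = int(rng.integers(150_000, 500_000))
        d_q = int(rng.integers(150_000, 500_000))
        regions = [
            (GenomicInterval(chrom, j_p - d_p, j_p), 1),
            (GenomicInterval(chrom, j_q, j_q + d_q), 1),
        ]
        arm_breakpoints[p_arm.name] = j_p - d_p
        arm_breakpoints[q_arm.name] = j_q + d_q
    elif structure == "idic":
        arm = q_arm if rng.random() < 0.5 else p_arm
        j = j_q if arm.arm == "q" else j_p
        d1 = int(rng.integers(400_000, 700_000))
        d2 = d1 + int(rng.integers(400_000, 600_000))
        if arm.arm == "q":
            regions = [
                (GenomicInterval(chrom, j, j + d1), 2),
                (GenomicInterval(chrom, j + d1, j + d2), 1),
            ]
            arm_breakpoints[arm.name] = j + d2
        else:
            regions = [
                (GenomicInterval(chrom, j - d1, j), 2),
                (GenomicInterval(chrom, j - d2, j - d1), 1),
            ]
            arm_breakpoints[arm.name] = j - d2
    else:
        raise ValueError(f"unknown structure {structure!r}")

    # fine mapping probes: the core panel plus specific clones distal to it
    calls: list[ProbeCall] = []
    for arm in (p_arm, q_arm):
        if panels.get(arm.name) is None:
            continue
        usable = [
            c
            for c in tracks.clones
            if c.primary.chrom == arm.chrom
            and c.primary.overlaps(arm.extent)
            and not c.alternates
            and c.segdup_fraction <= 0.5
        ]
        usable.sort(
            key=lambda c: (
                arm_distance(arm, arm.proximal_pos, c.proximal_edge(arm)),
                c.name,
            )
        )
        for clone in usable:
            signal = _signal_for(clone, regions)
            if signal != ABSENT and rng.random() < false_negative:
                signal = ABSENT
            elif signal == ABSENT and rng.random() < false_positive:
                signal = SINGLE
            calls.append(ProbeCall(clone, arm, signal))

    level = (
        float(rng.uniform(0.2, 1.0)) if mosaic_level is None else float(mosaic_level)
    )
    n_total = 16
    n_with = int(rng.binomial(n_total, level))

    case_id = case_id or f"sim-{seed}"
    obs = MarkerObservation(
        case_id=case_id,
        structure=structure,
        calls=calls,
        n_metaphases_total=n_total,
        n_metaphases_with_marker=n_with,
    )
    segments = _acgh_segments_for(regions, rng)
    truth = SimTruth(
        case_id=case_id,
        structure=structure,
        chrom=chrom,
        arm_breakpoints=arm_breakpoints,
        segments=[(r.chrom, r.start, r.end, c) for r, c in regions],
        content_bp=sum(r.width for r, _ in regions),
        mosaic_level=level,
        false_negative=false_negative,
        false_positive=false_positive,
    )
    return obs, segments, truth


# --------------------------------------------------------------------------
# File emission (same formats the analysis CLI consumes)

def write_genome_files(tracks: Tracks, outdir: str | Path) -> dict[str, Path]:
    """Write chrom.sizes / het.bed / clones.bed / segdups.bed under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "het_bed": outdir / "het.bed",
        "clones_bed": outdir / "clones.bed",
        "segdup_bed": outdir / "segdups.bed",
    }
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in tracks.assembly.chrom_lengths.items():
            fh.write(f"{name}\t{length}\n")
    with open(paths["het_bed"], "w") as fh:
        for b in sorted(tracks.het_blocks, key=lambda b: (b.region.chrom, b.region.start)):
            fh.write(f"{b.region.chrom}\t{b.region.start}\t{b.region.end}\n")
    with open(paths["clones_bed"], "w") as fh:
        for c in tracks.clones:
            alts = ",".join(f"{a.chrom}:{a.start}-{a.end}" for a in c.alternates) or "."
            fh.write(
                f"{c.primary.chrom}\t{c.primary.start}\t{c.primary.end}\t{c.name}"
                f"\t{alts}\t{c.segdup_fraction}\n"
            )
    with open(paths["segdup_bed"], "w") as fh:
        for iv in tracks.segdups:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return paths


def write_case_files(
    obs: MarkerObservation,
    segments: list[AcghSegment],
    truth: SimTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write calls.tsv / acgh.tsv / truth.json for one simulated case."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": outdir / f"{obs.case_id}.calls.tsv",
        "acgh": outdir / f"{obs.case_id}.acgh.tsv",
        "truth": outdir / f"{obs.case_id}.truth.json",
    }
    header = (
        "case_id\tprobe_name\tchrom\tstart\tend\tarm\tsignal\tstructure_hint"
        "\tn_metaphases_with_marker\tn_metaphases_total\n"
    )
    with open(paths["calls"], "w") as fh:
        fh.write(header)
        for c in obs.calls:
            fh.write(
                f"{obs.case_id}\t{c.probe.name}\t{c.probe.primary.chrom}"
                f"\t{c.probe.primary.start}\t{c.probe.primary.end}\t{c.arm.name}"
                f"\t{c.signal}\t{obs.structure}"
                f"\t{obs.n_metaphases_with_marker}\t{obs.n_metaphases_total}\n"
            )
    with open(paths["acgh"], "w") as fh:
        fh.write("chrom\tstart\tend\tmean_log2\tstart_lo\tstart_hi\tend_lo\tend_hi\n")
        for s in segments:
            su = s.start_uncertainty
            eu = s.end_uncertainty
            fh.write(
                f"{s.region.chrom}\t{s.region.start}\t{s.region.end}\t{s.mean_log2}"
                f"\t{su.start}\t{su.end}\t{eu.start}\t{eu.end}\n"
            )
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
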