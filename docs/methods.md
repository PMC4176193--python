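# Methods

This note documents the models and procedures `pericore` implements, the
defaults and why, and what the simulation-based tests do and do not show.

## Coordinates and interval arithmetic

Intervals are stored 0-based half-open internally; BED tracks load verbatim
and `chrN:A-B` locus strings keep their printed bounds, so a reported width
is always `B − A`. This matches how sizes are quoted in the cytogenetics
literature (e.g. a duplication of 15,371,616 bp quoted as 15.4 Mb, or a
236,020 bp probe window as 236 kb): coordinate differences, not inclusive
base counts. Sizes in Mb/kb are rounded half-up at the requested decimal.
Locus strings accept commas, stray spaces, and every dash variant found in
print (hyphen, en/em dash, minus sign).

Arms carry an orientation: distal (toward the telomere) means decreasing
coordinates on a p arm and increasing on a q arm. All distances along arms
use this signed convention, so the same code handles both arms.

Arm extents are derived from the heterochromatin track: the p/q boundary is
the midpoint of the chromosome's heterochromatin span (chromosome midpoint
when no block is annotated). This is only a bookkeeping split — junctions,
panels, and breakpoints never depend on the exact boundary position, only on
the het block edges.

## Panel design

**Junction.** On a p arm, euchromatin lies at smaller coordinates, so the
heterochromatin/euchromatin junction is the start of the arm's het block; on
a q arm it is the end. Arms with no annotated block get an *undefined*
junction — a value, not an error — mirroring assembly gaps at several human
arm roots.

**Specificity screen.** A clone with any placement on a different chromosome
is *excluded* (wrong chromosomal localization). Same-chromosome alternate
placements, or segmental-duplication coverage above `max_segdup_fraction`
(default 0.5), make it *cross-hybridizing* but still mappable; otherwise
*specific*. The threshold default is a policy choice, configurable; no
published cutoff exists for when segdup coverage defeats unique mapping.

**Tiling.** The core panel anchors at the eligible clone nearest the
junction (among ties, the one reaching farthest distally) and then greedily
adds, among clones whose proximal edge lies within `max_gap_bp` (default
50 kb) of the frontier, the one extending farthest; it stops at a cumulative
span of `target_span_bp` (default 700 kb, the field's usual proximal-core
coverage) or `max_clones` (7). Greedy farthest-reach is optimal for interval
cover; the test suite asserts equality with an exhaustive minimum over
random libraries of ≤ 15 clones rather than assuming it. A panel is
*complete* when it is junction-anchored (distance 0 within
`proximal_slack_bp`), meets the span target, and has 3–7 clones; failure
states distinguish a missing junction from screening-depleted proximal
coverage (the segdup case).

**Statistics.** `d_het_prox` is the junction-to-proximal-clone-edge distance
floored at zero (clones straddling the junction count as 0); `core_span` is
proximal edge of the proximal clone to distal edge of the distal clone.
Which clone edges define the span is not standardized; this choice is
isolated in `panel_stats` so it can be swapped. The set-level mean span is
taken over panels with both a proximal and a distal clone. The published
per-arm bookkeeping table (43 human arms) ships as data in `panels.py`;
clone base-pair extents are not part of it, so tests use generated fixtures
wherever clone coordinates matter.

## Marker characterization

**Classification.** A marker is heterochromatic-only iff every
euchromatic-probe call is absent; any diminished/single/double signal makes
it euchromatic; no calls → undetermined.

**Breakpoints.** With probes ordered proximal→distal, the breakpoint between
the most distal present probe *P* and the most proximal absent probe *A*
distal of it is bounded by the convex hull of both clone extents. The hull
is deliberately conservative in both directions: a full ("single") signal
only guarantees ≥ ~80% probe overlap, so the true breakpoint can hide in
*P*'s distal margin, and FISH cannot exclude a sub-resolution sliver inside
*A*. For the same reason an all-present arm yields an *open-distal* interval
that still includes the last clone. A diminished signal places the
breakpoint inside that clone. An absent probe between present probes flags
an `internal_deletion` and produces one hull interval per transition, plus
an open-distal interval when content resumes past the last probe.

**Dosage.** Signals map to marker copies (double = 2, single = 1,
diminished = partial, absent = 0); total dosage adds the two constitutive
homologs. Runs of equal copies merge into segments covering the hull of
their clones. Copy number must be non-increasing distally — isodicentrics
may step 2 → 1 → 0 across asymmetric breakpoints — and a distal rise without
an internal-deletion flag raises a conflict (mutually inconsistent calls,
e.g. cross-hybridization).

**Content bounds.** Per arm, the minimum euchromatic content is the
junction-to-nearest-breakpoint-bound arm distance clamped at zero, the
maximum the distance to the farthest bound (+∞ for open-distal); totals sum
over arms, and heterochromatic-only markers are (0, 0) by definition. With
an internal deletion the most distal interval bounds the arm, which
overstates the minimum by the deleted width — flagged cases should be read
with that in mind.

**Mosaicism.** The mosaic fraction is `k/n` marker-positive metaphases with
a two-sided exact Clopper–Pearson interval (α = 0.05) from beta quantiles;
no interval convention is standard in this setting, so the exact interval
was chosen for its coverage guarantee at the small *n* (≈16) typical of a
metaphase workup. `required_metaphases(m, c)` solves `1 − (1−m)^n ≥ c`,
floored at the conventional 16 spreads; it is exposed as a planning helper
and makes no claim to reproduce any particular lab's policy.

## Array-CGH integration

Segments (e.g. ADM-2 output) are consumed, never computed. Gain/loss calls
use |mean log2| ≥ 0.3 by default (configurable; segmentation software
reports no universal cutoff). Each edge of a segment may carry a
boundary-uncertainty interval — the last-normal to first-aberrant probe pair
— supplied explicitly in the TSV; absent that, the bare segment edge is used
as a zero-width boundary. Refinement is the intersection of the FISH
interval with a boundary interval of a gain segment on the same arm;
refining with the FISH interval itself is a no-op, and disjoint inputs raise
an assay-conflict error that the pipeline converts into a report flag
(conflicts are data). Arms whose FISH probes are uninformative can take a
breakpoint directly from a gain segment's distal boundary interval.

## Phenotype risk

Critical/noncritical region boundaries are user-supplied annotation (one TSV
row per arm) — they are curated knowledge that changes over time and is
deliberately not shipped; test fixtures carry synthetic maps. A marker is
`likely_benign` when heterochromatic-only or when all dosed segments lie
within annotated noncritical regions; `likely_pathogenic` when any segment
with ≥ 1 marker copy overlaps a critical region; `uncertain` when an
involved arm's boundaries are unknown or segments fall only in the gap
between the regions — gaps read as uncertain rather than benign because
gap-region dosage has accompanied (mild) phenotypes. Mosaic fraction below
0.30 (configurable policy value) appends an attenuation note but never
changes the label: how mosaic level modulates risk is not formalized
anywhere, so the note is advisory only.

## Simulation

The generator emulates the pericentromeric landscape the panels target:
6 chromosomes of 60–160 Mb, heterochromatic blocks of 2–8 Mb at both arm
roots, one acrocentric chromosome whose p arm carries no clones, and a
clone library of BAC-like 150–200 kb inserts tiling the proximal 1.5 Mb of
euchromatin on every non-acrocentric arm with 10–40 kb overlaps, plus decoy
clones (off-target placements, heavy segdup coverage) for the screen. These
defaults are fixed, realistic values for the scale of the problem, chosen
once; everything is deterministic under the seed.

Marker cases plant known truth: rings and minutes take one breakpoint per
arm (0.4–1.2 Mb and 0.15–0.5 Mb of euchromatin per arm respectively), an
isodicentric takes two asymmetric breakpoints on one arm (proximal
tetrasomic segment ≥ 0.4 Mb, trisomic margin 0.4–0.6 Mb), and het-only cases
place both breakpoints inside the heterochromatin. The observation model:
a probe overlapping content by < 10 kb is absent (the FISH detectability
floor), ≥ 80% of its length is a full signal (double when ≥ 80% lies in the
two-copy region), anything between is diminished; both thresholds are
simulator policy, configurable in one place. Array-CGH gains snap to a 43 kb
oligo grid with the flanking probe pair as boundary uncertainty, and
metaphase counts are binomial at the planted mosaic level (n = 16).

The planted region widths are deliberately at least two clone pitches for
rings/idics so that every integer copy level is witnessed by a fully
embedded probe; minutes may be sub-probe by design and are checked on
classification, breakpoint containment, and content bounds only.

**What passing tests show** — that the inference is conservative and exact
under its own observation model: over ≥ 500 noiseless cases all planted
breakpoints fall inside inferred intervals, classes and content bounds
hold, and all dosage levels are reproduced; under a 5% probe false-call
rate breakpoint containment stays above 90% (a regression guard, not a
claim about laboratory error rates). **What they do not show** — real FISH
signal ambiguity (intensity does not step cleanly at 80% overlap),
cross-hybridization structure between real paralogous duplications,
assembly errors at arm roots, or culture artifacts in metaphase counts.

## Numerical and degenerate-input choices

- Rounding of reported sizes: decimal half-up (reproduces the printed
  13,364,286 → 13.4 behaviour); internal arithmetic stays in integers/bp.
- Tie-breaks: equal arm distances order by clone name; panel selection is
  therefore order-independent, and shuffling a library never changes
  screening labels or the selected panel.
- Zero-width intervals are legal everywhere (a point locus parses, abutting
  intervals intersect in a zero-width interval).
- Empty inputs are values where the domain has a meaning for them (no het
  block → undefined junction; empty library → unavailable panel; empty
  segment table → not-found) and errors where they do not (no calls on an
  arm, zero metaphases).
- Open-ended content uses an infinity sentinel internally, `null` in JSON,
  and renders as "> X Mb".
- Report JSON serializes with sorted keys; serialize → parse → serialize is
  byte-identical.
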