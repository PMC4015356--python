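# Methods

This note documents the models, algorithms and constants behind `ideoplot`,
the design choices made where more than one reasonable definition existed,
and what the synthetic fixtures do and do not establish.

## Coordinate conventions

Band intervals follow the UCSC cytoBand dialect internally: 0-based,
half-open `[start, end)`, with the gieStain vocabulary
`gneg, gpos25, gpos50, gpos75, gpos100, acen, gvar, stalk`. User-facing
`POS`/`END` values are 1-based and inclusive, matching how biologists quote
SNP coordinates; they are converted on ingest. The affine base-pair→pixel
map sends the first displayed base to the track top and the last to the
track bottom, so zoomed and whole-chromosome tracks share one code path.
Chromosome names are stored bare (`1`–`22`, `X`, `Y`); a `chr` prefix and
lower-case `x/y` are tolerated on input because real files vary.
Non-canonical contigs (chrM, random/alt scaffolds) in cytoBand files are
skipped silently, since genuine UCSC dumps contain them.

## The bundled genome

The packaged band table (`data/hg19_bands_synthetic.txt`, UCSC dialect) is
a constructed stand-in at hg19 scale, generated once and shipped as text:

- chromosome lengths are the exact hg19 values (chr1 = 249,250,621 bp …);
- centromere (acen) spans, the stalk bands on the five acrocentric p-arms
  (13, 14, 15, 21, 22), and the large constitutive-heterochromatin (gvar)
  blocks at 1q12, 9q12, 16q11.2, Yq12 and the acrocentric p11.2 regions
  follow the published coordinates to ~100 kb;
- the grey-band (gneg/gpos) pattern filling the arms is generated
  deterministically with realistic 4–12 Mb band sizes, not measured.

Figures that shade bands are therefore structurally faithful (waists,
stalks, heterochromatin in the right places) but the arm banding pattern is
illustrative. Analyses that need the measured hg19 banding should pass a
genuine `cytoBand.txt` via `--cytoband` / `load_cytoband`.

## Glyph spacing

Let runs (groups of glyphs at identical anchors, fanned into horizontal
lanes) have anchors `a_1 ≤ … ≤ a_n`, diameter `d`, on a track of extent
`E`. All three methods preserve genomic order.

**Standard** is a greedy sweep `y_i = max(a_i, y_{i-1} + d)` followed by a
bottom-up pass `y_i = min(y_i, y_{i+1} - d)` anchored at `y_n ≤ E`, so an
overflowing tail is pushed back inside without reordering.

**Equal** places run *i* at `E·i/(n+1)`. The interval is fixed by this
definition, so one-diameter separation is achievable exactly when
`E ≥ (n+1)·d` — slightly stricter than the `n·d ≤ E` capacity bound of the
other two methods.

**Proximity** solves `min Σ (y_i − a_i)²` subject to `y_{i+1} − y_i ≥ d`.
Substituting `z_i = y_i − i·d` turns the gap constraints into monotonicity
of `z`, so the optimum is the isotonic L2 projection of the shifted
anchors, computed by pool-adjacent-violators. This is exactly the intuitive
cluster-merge picture: overlapping neighbors coalesce into a cluster
centered on the mean of its members' anchors and spread at minimum
separation, repeated to fixpoint. The test suite verifies optimality
against an independent exact oracle that enumerates all 2^(n−1) active-set
patterns of the KKT system for n ≤ 8 (agreement within 1e-6 in total
squared displacement). Final clamping to the track bounds can in principle
trade optimality for containment; it only engages when anchors sit within
half a diameter of a track end.

When a track cannot hold its runs (`n·d > E`), standard and proximity fall
back to equal spacing with a warning rather than failing: a plotting tool
should always produce a plot.

## Color and shape assignment

- **list** — a fixed constant of ten well-separated, colorblind-aware
  colors (`#e6194b, #006ee6, #3cb44b, #f58230, #911eb4, #46f0f0, #f0be14,
  #f032e6, #806928, #000000`). Requests beyond ten raise an error directing
  users to the generator, rather than silently switching.
- **generator** — hues at `i·360/n` degrees, fixed S = 0.78, V = 0.90.
  Minimum pairwise hue separation is exactly 360/n° (up to 8-bit rounding).
- **web** — the 216-color lattice `{0,51,102,153,204,255}³`, shuffled by
  the seed and drawn without replacement so the assignment stays injective
  for up to 216 phenotypes.
- **random** — independent uniform 8-bit channels; no separation guarantee,
  by design.
- **group** — base hues from the generator over the groups in
  first-appearance order; within a group, constant hue with lightness
  increasing linearly from 0.30 to 0.75 in legend order (single-member
  groups sit at 0.50). Saturation is floored at 0.5 so the gradient stays
  chromatic.
- **POSCOLOR** codes 0–7 map to a fixed table — black, red, blue, green,
  orange, purple, brown, magenta — with 0 (black) the default mark color.
- **Ancestry shapes** are circle, square, triangle in first-appearance
  order; the fourth and later groups reuse the circle, capping the figure
  at three distinguishable shapes. Square sides are scaled to match the
  circle's area so no shape dominates visually.

One integer seed (default 7) drives every stochastic choice; `list`,
`generator` and `group` ignore it entirely, so their output never varies.

## Rendering

The figure is first composed as a flat list of tagged primitive commands
(lines, rectangles, rounded rectangles, circles, polygons, text) in canvas
coordinates; backends then rasterize with Pillow or serialize to SVG 1.1
via a small built-in writer. This makes the renderer testable at the
command level (counting marks, glyphs and legend entries) independently of
pixels, and makes output a pure function of (records, genome, config) —
re-rendering is byte-identical.

Numerical/visual constants, all documented and pinned by tests:

- canvas 1080×780 px at the default 300 DPI; the high-resolution option
  scales pixel dimensions 4× and stamps 1200 DPI into the PNG pHYs chunk;
- whole-genome mode: two rows (chromosomes 1–12 / 13–Y), one shared
  bp-per-pixel scale anchored to the longest chromosome;
- transverse marks: width 1.6 px (halved by thin-lines), opacity 0.4 under
  trans-lines; translucent marks are alpha-composited so k stacked marks
  reach coverage `1−0.6^k`, letting density read as darkness;
- chromosome boundary 1.4 px, doubled by thick-boundary; glyph diameter
  16 % of the per-chromosome cell (halved by small-circle); big-font scales
  label text 1.5× without touching glyphs;
- grey ramp for gpos bands: 255 (gneg), 201, 150, 99, 40; heterochromatin
  (acen + gvar) dark blue `#2b3e8f`; stalks light blue `#99b7e6`;
- z-order follows input-file order within each layer, so later regions
  plot over earlier ones (the two-color CNV overlay idiom).

Degenerate inputs are handled explicitly: an empty record list renders bare
ideograms; records excluded by a zoom window are dropped with a warning,
not an error; notes longer than ten characters are truncated with a
warning (counting characters, not bytes).

## Synthetic study generator

`generate_synthetic_input` emulates the three study shapes the tool is
used for — catalog-style SNP/phenotype points, dense array-coverage line
sets, and CNV-like regions — with uniform positions within chromosome
bounds, round-robin phenotypes (every label appears), regions spanning
0.2–2 % of their chromosome, and optional note/ancestry/group/poscolor
columns. It is seeded and reproducible, and every generated file re-parses
with zero warnings (a property test).

What it does not emulate: real positional clustering (gene-dense regions,
LD blocks, the MHC), realistic phenotype–locus pleiotropy structure, or
ancestry-by-phenotype correlation. Passing tests therefore establish the
plotting pipeline's contracts — parsing, placement, coloring, compositing,
determinism — not that figures from real catalogs are scientifically
meaningful; that depends on the user's data.

## Problem sizes

Default test and acceptance runs use 120-record studies on the full
24-chromosome genome, spacing property suites of 1000 random instances per
method in the tests (200 per method in the acceptance report), and 200–400
proximity-vs-QP comparisons at n ≤ 8 (the exact oracle
enumerates 2^(n−1) active sets, so it is kept at small n where it is
provably exhaustive). These sizes exercise every code path, including
capacity fallback on the small Y-chromosome track.

## Known limitations

- Only the bundled hg19-scale assembly, user UCSC-format band files and
  synthetic genomes; no other builds, no liftover.
- Glyphs render on one side of the chromosome only.
- PNG and SVG only; no PDF or interactive output.
- The equal-spacing definition cannot guarantee one-diameter separation in
  the narrow band `n·d ≤ E < (n+1)·d` (see above).
- Band-level shading of the bundled genome is illustrative along the arms
  (see "The bundled genome").
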