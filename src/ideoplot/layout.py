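"""Canvas layout: genome-to-pixel mapping and glyph spacing.

Chromosomes are drawn as vertical tracks (p-arm at the top). A whole-genome
plot arranges the 24 tracks in two rows — chromosomes 1-12 above, 13-22
plus X and Y below — with one shared base-pair-per-pixel scale so relative
chromosome sizes stay truthful. A zoomed plot devotes the whole canvas to
one chromosome or sub-region.

Glyphs attached to positions are first anchored at the pixel image of
their base-pair coordinate and then *spaced* so they do not overlap:

* ``standard`` — a greedy top-to-bottom sweep pushing each run of
  co-located glyphs down just enough to clear the previous run.
* ``equal`` — runs placed at equal intervals down the track, genomic
  order preserved.
* ``proximity`` — the order-preserving placement with pairwise gaps of at
  least one glyph diameter that minimizes the total squared displacement
  from the anchors, computed by merging overlapping neighbors into
  clusters centered on their mean anchor (pool-adjacent-violators on the
  gap-shifted anchors, which yields the exact least-squares optimum).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .annotations import AnnotationRecord
from .errors import UsageError
from .genome import GenomeAssembly, normalize_chrom

__all__ = [
    "ZoomRegion",
    "Track",
    "CanvasGeometry",
    "GlyphSlot",
    "parse_zoom",
    "bp_to_y",
    "make_slots",
    "space_standard",
    "space_equal",
    "space_proximity",
    "layout_chromosomes",
]


@dataclass(frozen=True, slots=True)
class ZoomRegion:
    """A chromosome, optionally narrowed to a [start_bp, end_bp] window."""

    chrom: str
    start_bp: int | None = None
    end_bp: int | None = None

    def __post_init__(self) -> None:
        if (self.start_bp is None) != (self.end_bp is None):
            raise ValueError("zoom start and end must be given together")
        if self.start_bp is not None and self.start_bp >= self.end_bp:
            raise ValueError(
                f"zoom start ({self.start_bp}) must precede end ({self.end_bp})"
            )


_ZOOM_RE = re.compile(r"^(?P<chrom>\w+)(?::(?P<start>\d+)\s*[-–—]\s*(?P<end>\d+))?$")


def parse_zoom(spec: str) -> ZoomRegion:
    """Parse a zoom request: ``"7"`` (whole chromosome) or ``"7:10000-20000"``.

    Hyphen, en-dash and em-dash are all accepted as the range separator.
    """
    m = _ZOOM_RE.match(spec.strip())
    if not m:
        raise UsageError(f"malformed zoom specification {spec!r}")
    chrom = normalize_chrom(m.group("chrom"))
    if chrom is None:
        raise UsageError(f"unknown chromosome in zoom specification {spec!r}")
    if m.group("start") is None:
        return ZoomRegion(chrom)
    start, end = int(m.group("start")), int(m.group("end"))
    if start >= end:
        raise UsageError(f"zoom range start must precede end in {spec!r}")
    return ZoomRegion(chrom, start, end)


@dataclass(frozen=True, slots=True)
class Track:
    """One chromosome's strip on the canvas."""

    chrom: str
    x_px: float            # left edge of the chromosome body
    y_top_px: float
    height_px: float       # vertical extent of the displayed region
    body_w_px: float       # drawn chromosome width
    start_bp: int          # first displayed base (1-based)
    end_bp: int            # last displayed base (1-based)

    @property
    def y_bottom_px(self) -> float:
        return self.y_top_px + self.height_px

    @property
    def x_right_px(self) -> float:
        return self.x_px + self.body_w_px


@dataclass
class CanvasGeometry:
    """Full canvas plan: size, margins and one track per chromosome."""

    width_px: float
    height_px: float
    tracks: dict[str, Track]
    px_per_bp: float
    glyph_d_px: float
    cell_w_px: float
    title_h_px: float
    legend_h_px: float
    scale: float = 1.0


def bp_to_y(pos_bp: int, track: Track) -> float:
    """Affine map from a base-pair position to a canvas y coordinate.

    Position ``track.start_bp`` maps to the track top and ``track.end_bp``
    to the track bottom; strictly increasing in between.
    """
    span = track.end_bp - track.start_bp
    if span == 0:
        return track.y_top_px
    return track.y_top_px + (pos_bp - track.start_bp) / span * track.height_px


@dataclass
class GlyphSlot:
    """A glyph's anchor and (after spacing) its placed position."""

    record_index: int
    chrom: str
    anchor_y_px: float
    glyph_d_px: float
    placed_y_px: float | None = None
    lane: int = 0


@dataclass
class _Run:
    """Co-located slots fanned into consecutive lanes at one y."""

    anchor: float
    slots: list[GlyphSlot] = field(default_factory=list)


def make_slots(
    records: Sequence[AnnotationRecord],
    indices: Iterable[int],
    track: Track,
    glyph_d: float,
) -> list[GlyphSlot]:
    """Build anchor-sorted slots for the given record indices on one track."""
    slots = [
        GlyphSlot(i, records[i].chrom, bp_to_y(records[i].pos_bp, track), glyph_d)
        for i in indices
    ]
    slots.sort(key=lambda s: (s.anchor_y_px, s.record_index))
    return slots


def _group_runs(slots: Sequence[GlyphSlot]) -> list[_Run]:
    runs: list[_Run] = []
    for slot in slots:
        if runs and math.isclose(slot.anchor_y_px, runs[-1].anchor, abs_tol=1e-9):
            runs[-1].slots.append(slot)
        else:
            runs.append(_Run(slot.anchor_y_px, [slot]))
    return runs


def _emit(runs: list[_Run], placed: Sequence[float]) -> list[GlyphSlot]:
    out: list[GlyphSlot] = []
    for run, y in zip(runs, placed):
        for lane, slot in enumerate(run.slots):
            out.append(replace(slot, placed_y_px=float(y), lane=lane))
    return out


def _capacity_exceeded(n_runs: int, glyph_d: float, top: float, bottom: float) -> bool:
    return n_runs * glyph_d > (bottom - top) + 1e-9


def space_equal(
    slots: Sequence[GlyphSlot], top: float, bottom: float
) -> tuple[list[GlyphSlot], list[str]]:
    """Place runs at equal intervals spanning the track."""
    runs = _group_runs(slots)
    n = len(runs)
    if n == 0:
        return [], []
    extent = bottom - top
    placed = [top + extent * (i + 1) / (n + 1) for i in range(n)]
    return _emit(runs, placed), []


def space_standard(
    slots: Sequence[GlyphSlot], top: float, bottom: float
) -> tuple[list[GlyphSlot], list[str]]:
    """Greedy top-to-bottom sweep: push each run down to clear the last.

    A final pass pushes runs back up if the lowest run has escaped the
    track bottom. Falls back to equal spacing when the runs cannot fit.
    """
    runs = _group_runs(slots)
    if not runs:
        return [], []
    d = runs[0].slots[0].glyph_d_px
    if _capacity_exceeded(len(runs), d, top, bottom):
        placed, _ = space_equal(slots, top, bottom)
        return placed, ["glyph capacity exceeded; fell back to equal spacing"]
    placed = []
    prev = -math.inf
    for run in runs:
        y = max(run.anchor, prev + d, top)
        placed.append(y)
        prev = y
    # bottom-overflow: walk back up, never reordering
    limit = bottom
    for i in range(len(placed) - 1, -1, -1):
        if placed[i] > limit:
            placed[i] = limit
        limit = placed[i] - d
    return _emit(runs, placed), []


def _pava_mean(values: Sequence[float]) -> list[float]:
    """Pool-adjacent-violators: the non-decreasing L2 projection of values."""
    level: list[float] = []
    weight: list[int] = []
    for v in values:
        level.append(v)
        weight.append(1)
        while len(level) > 1 and level[-2] > level[-1] - 1e-15:
            w = weight[-2] + weight[-1]
            m = (level[-2] * weight[-2] + level[-1] * weight[-1]) / w
            level.pop(); weight.pop()
            level[-1], weight[-1] = m, w
    out: list[float] = []
    for m, w in zip(level, weight):
        out.extend([m] * w)
    return out


def space_proximity(
    slots: Sequence[GlyphSlot], top: float, bottom: float
) -> tuple[list[GlyphSlot], list[str]]:
    """Least-squares spacing: minimal displacement under the min-gap rule.

    Writing the run positions as ``y_i = z_i + i*d`` turns the gap
    constraints ``y_{i+1} - y_i >= d`` into monotonicity of ``z``, so the
    optimum is the isotonic (pool-adjacent-violators) projection of the
    shifted anchors — exactly the cluster-merge picture: overlapping
    neighbors collapse into a cluster centered on the mean of their
    anchors and spread at minimum separation. Results are finally clamped
    to the track bounds.
    """
    runs = _group_runs(slots)
    if not runs:
        return [], []
    d = runs[0].slots[0].glyph_d_px
    if _capacity_exceeded(len(runs), d, top, bottom):
        placed, _ = space_equal(slots, top, bottom)
        return placed, ["glyph capacity exceeded; fell back to equal spacing"]
    shifted = [run.anchor - i * d for i, run in enumerate(runs)]
    fitted = _pava_mean(shifted)
    placed = [z + i * d for i, z in enumerate(fitted)]
    # clamp into the track, preserving gaps
    if placed[0] < top:
        for i in range(len(placed)):
            placed[i] = max(placed[i], top + i * d)
    if placed[-1] > bottom:
        for i in range(len(placed) - 1, -1, -1):
            placed[i] = min(placed[i], bottom - (len(placed) - 1 - i) * d)
    return _emit(runs, placed), []


SPACING_METHODS = {
    "standard": space_standard,
    "equal": space_equal,
    "proximity": space_proximity,
}


# ---------------------------------------------------------------------------
# canvas planning

#: Base canvas size in px at scale 1 (300 DPI output).
BASE_WIDTH = 1080.0
BASE_HEIGHT = 780.0
MARGIN = 24.0
TITLE_H = 40.0
LEGEND_ROW_H = 26.0
TRACK_LABEL_H = 16.0
#: Chromosomes drawn per row in whole-genome mode (1-12 above, the rest below).
ROW_SPLIT = 12
#: Glyph diameter as a fraction of the per-chromosome cell width.
GLYPH_FRACTION = 0.16
BODY_FRACTION = 0.22


def layout_chromosomes(
    genome: GenomeAssembly,
    *,
    zoom: ZoomRegion | None = None,
    chrom_only: bool = False,
    records: Sequence[AnnotationRecord] = (),
    small_circle: bool = False,
    n_legend_rows: int = 0,
    title: bool = False,
    scale: float = 1.0,
) -> CanvasGeometry:
    """Plan the canvas: which chromosomes appear where, at what scale."""
    if zoom is not None:
        if zoom.chrom not in genome:
            raise UsageError(f"zoom chromosome {zoom.chrom} not in genome")
        names = [zoom.chrom]
    elif chrom_only:
        with_data = {r.chrom for r in records}
        names = [n for n in genome.names if n in with_data]
        if not names:
            names = list(genome.names)
    else:
        names = list(genome.names)

    width = BASE_WIDTH * scale
    height = BASE_HEIGHT * scale
    margin = MARGIN * scale
    title_h = (TITLE_H if title else 12.0) * scale
    legend_h = (n_legend_rows * LEGEND_ROW_H + (8.0 if n_legend_rows else 0.0)) * scale
    label_h = TRACK_LABEL_H * scale

    plot_top = margin + title_h
    plot_bottom = height - margin - legend_h
    plot_h = plot_bottom - plot_top

    if zoom is not None:
        cdef = genome.chromosome(zoom.chrom)
        start = zoom.start_bp if zoom.start_bp is not None else 1
        end = zoom.end_bp if zoom.end_bp is not None else cdef.length_bp
        cell_w = (width - 2 * margin)
        track_h = plot_h - label_h
        px_per_bp = track_h / max(end - start, 1)
        glyph_d = 14.0 * scale
        body_w = 36.0 * scale
        track = Track(
            chrom=zoom.chrom,
            x_px=margin + cell_w * 0.18,
            y_top_px=plot_top + label_h,
            height_px=track_h,
            body_w_px=body_w,
            start_bp=start,
            end_bp=end,
        )
        tracks = {zoom.chrom: track}
        if small_circle:
            glyph_d /= 2
        return CanvasGeometry(
            width, height, tracks, px_per_bp, glyph_d, cell_w, title_h, legend_h, scale
        )

    if len(names) <= ROW_SPLIT:
        rows = [names]
    else:
        rows = [names[:ROW_SPLIT], names[ROW_SPLIT:]]
    n_rows = len(rows)
    cols = max(len(r) for r in rows)
    cell_w = (width - 2 * margin) / cols
    row_h = plot_h / n_rows
    track_h_max = row_h - label_h
    longest = max(genome.chromosome(n).length_bp for n in names)
    px_per_bp = track_h_max / longest
    body_w = cell_w * BODY_FRACTION
    glyph_d = cell_w * GLYPH_FRACTION
    if small_circle:
        glyph_d /= 2

    tracks = {}
    for ri, row in enumerate(rows):
        y0 = plot_top + ri * row_h + label_h
        for ci, name in enumerate(row):
            length = genome.chromosome(name).length_bp
            tracks[name] = Track(
                chrom=name,
                x_px=margin + ci * cell_w + cell_w * 0.12,
                y_top_px=y0,
                height_px=length * px_per_bp,
                body_w_px=body_w,
                start_bp=1,
                end_bp=length,
            )
    return CanvasGeometry(
        width, height, tracks, px_per_bp, glyph_d, cell_w, title_h, legend_h, scale
    )
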