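"""Figure composition and output backends.

``build_scene`` turns validated records + a genome + a :class:`PlotConfig`
into a flat drawing-command list (see :mod:`ideoplot.scene`); ``render``
rasterizes that list to PNG (via Pillow, with physical-resolution pHYs
metadata) or serializes it as SVG 1.1. Rendering is a pure function of
(records, genome, config): identical calls produce byte-identical output.
"""

from __future__ import annotations

import io
import xml.sax.saxutils as saxutils
from dataclasses import dataclass, field

from PIL import Image, ImageDraw, ImageFont

from .annotations import ParsedInput, validate_against_genome
from .colors import (
    DEFAULT_SEED,
    ColorAssignment,
    RGBColor,
    Shape,
    ShapeAssignment,
    assign_colors,
    assign_shapes,
    poscolor_lookup,
)
from .errors import UsageError
from .genome import ChromosomeDef, CytoBand, GenomeAssembly, Stain
from .layout import (
    SPACING_METHODS,
    CanvasGeometry,
    GlyphSlot,
    Track,
    ZoomRegion,
    bp_to_y,
    layout_chromosomes,
    make_slots,
)
from .scene import (
    CircleCmd,
    DrawCmd,
    LineCmd,
    PolygonCmd,
    RectCmd,
    RoundedRectCmd,
    TextCmd,
)

__all__ = [
    "PlotConfig",
    "RenderedImage",
    "DEFAULT_DPI",
    "HIGH_RES_DPI",
    "TRANS_ALPHA",
    "stain_to_style",
    "build_scene",
    "render",
]

#: Output resolution metadata: default and the high-resolution (-z) value.
DEFAULT_DPI = 300
HIGH_RES_DPI = 1200
#: Transverse-mark opacity under the transparent-lines flag.
TRANS_ALPHA = 0.4
#: Base stroke width (canvas units) of transverse marks; thin-lines halves it.
MARK_W = 1.6
#: Base chromosome boundary stroke; thick-boundary doubles it.
BOUNDARY_W = 1.4
#: Base legend/annotation font size; big-font scales it by 1.5.
FONT_PX = 11.0
BIG_FONT_FACTOR = 1.5

_WHITE = RGBColor(255, 255, 255)
_BLACK = RGBColor(0, 0, 0)

_STAIN_FILL: dict[Stain, RGBColor] = {
    Stain.GNEG: _WHITE,                      # R-bands: gene-rich, white
    Stain.GPOS25: RGBColor(201, 201, 201),   # G-bands: greys of
    Stain.GPOS50: RGBColor(150, 150, 150),   # increasing darkness
    Stain.GPOS75: RGBColor(99, 99, 99),
    Stain.GPOS100: RGBColor(40, 40, 40),
    Stain.ACEN: RGBColor(43, 62, 143),       # heterochromatin: dark blue
    Stain.GVAR: RGBColor(43, 62, 143),
    Stain.STALK: RGBColor(153, 183, 230),    # rRNA stalks: light blue
}


def stain_to_style(stain: Stain) -> RGBColor:
    """Fill color for a gieStain class."""
    return _STAIN_FILL[Stain(stain)]


@dataclass
class PlotConfig:
    """Every rendering option, with the documented defaults."""

    title: str = ""
    out_format: str = "png"
    spacing: str = "standard"
    color_method: str | None = None      # None: list if <=10 phenotypes else generator
    high_res: bool = False
    chrom_only: bool = False
    small_circle: bool = False
    outline_circle: bool = False
    zoom: ZoomRegion | None = None
    include_annotation: bool = False
    trans_lines: bool = False
    thin_lines: bool = False
    thick_boundary: bool = False
    big_font: bool = False
    shade_chromatin: bool = False
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.out_format not in ("png", "svg"):
            raise UsageError(
                f"unsupported output format {self.out_format!r}; choose png or svg"
            )
        if self.spacing not in SPACING_METHODS:
            raise UsageError(
                f"unknown spacing method {self.spacing!r}; "
                "choose standard, equal or proximity"
            )
        if self.color_method is not None and self.color_method not in (
            "random", "web", "generator", "group", "list"
        ):
            raise UsageError(f"unknown color method {self.color_method!r}")

    @property
    def dpi(self) -> int:
        return HIGH_RES_DPI if self.high_res else DEFAULT_DPI


@dataclass
class RenderedImage:
    """Finished output: encoded bytes plus declared geometry/metadata."""

    payload: bytes
    width_px: int
    height_px: int
    dpi: int
    format: str


# ---------------------------------------------------------------------------
# scene composition


def draw_chromosome(
    track: Track,
    chrom_def: ChromosomeDef,
    bands: tuple[CytoBand, ...],
    config: PlotConfig,
    scale: float,
) -> list[DrawCmd]:
    """Capsule outline with a centromere waist; band shading under -x."""
    cmds: list[DrawCmd] = []
    stroke_w = BOUNDARY_W * scale * (2.0 if config.thick_boundary else 1.0)
    x, w = track.x_px, track.body_w_px
    radius = w / 2 * 0.85

    cen_s = max(chrom_def.centromere_start_bp, track.start_bp)
    cen_e = min(chrom_def.centromere_end_bp, track.end_bp)
    has_waist = cen_s < cen_e
    y_cs = bp_to_y(cen_s, track) if has_waist else None
    y_ce = bp_to_y(cen_e, track) if has_waist else None

    if config.shade_chromatin:
        inset = w * 0.12
        for band in bands:
            lo = max(band.start_bp + 1, track.start_bp)
            hi = min(band.end_bp, track.end_bp)
            if lo > hi:
                continue
            y0, y1 = bp_to_y(lo, track), bp_to_y(hi, track)
            cmds.append(
                RectCmd(
                    tag="band",
                    x=x + inset,
                    y=y0,
                    w=w - 2 * inset,
                    h=max(y1 - y0, 0.5),
                    fill=stain_to_style(band.stain),
                )
            )

    fill = None if config.shade_chromatin else _WHITE
    if has_waist:
        cmds.append(
            RoundedRectCmd(
                tag="chrom-outline", x=x, y=track.y_top_px,
                w=w, h=max(y_cs - track.y_top_px, 1.0),
                radius=radius, fill=fill, stroke=_BLACK, stroke_w=stroke_w,
            )
        )
        cmds.append(
            RoundedRectCmd(
                tag="chrom-outline", x=x, y=y_ce,
                w=w, h=max(track.y_bottom_px - y_ce, 1.0),
                radius=radius, fill=fill, stroke=_BLACK, stroke_w=stroke_w,
            )
        )
        y_mid = (y_cs + y_ce) / 2
        waist_fill = stain_to_style(Stain.ACEN) if config.shade_chromatin else fill
        cmds.append(
            PolygonCmd(
                tag="centromere",
                points=(
                    (x, y_cs), (x + w, y_cs), (x + w * 0.62, y_mid),
                    (x + w, y_ce), (x, y_ce), (x + w * 0.38, y_mid),
                ),
                fill=waist_fill, stroke=_BLACK, stroke_w=stroke_w,
            )
        )
    else:
        cmds.append(
            RoundedRectCmd(
                tag="chrom-outline", x=x, y=track.y_top_px,
                w=w, h=track.height_px,
                radius=radius, fill=fill, stroke=_BLACK, stroke_w=stroke_w,
            )
        )

    label_px = FONT_PX * scale
    cmds.append(
        TextCmd(
            tag="track-label", x=x + w / 2, y=track.y_top_px - label_px * 1.3,
            text=track.chrom, font_px=label_px, anchor="mt", fill=_BLACK,
        )
    )
    return cmds


def draw_position_marks(
    records, indices, track: Track, config: PlotConfig, scale: float
) -> list[DrawCmd]:
    """One transverse line per point record, one filled band per region."""
    cmds: list[DrawCmd] = []
    alpha = TRANS_ALPHA if config.trans_lines else 1.0
    line_w = MARK_W * scale * (0.5 if config.thin_lines else 1.0)
    for i in indices:
        rec = records[i]
        color = poscolor_lookup(rec.poscolor or 0).with_alpha(alpha)
        if rec.is_region:
            y0 = bp_to_y(rec.pos_bp, track)
            y1 = bp_to_y(rec.end_bp, track)
            cmds.append(
                RectCmd(
                    tag="mark-region",
                    x=track.x_px, y=y0,
                    w=track.body_w_px, h=max(y1 - y0, 0.6),
                    fill=color,
                )
            )
        else:
            y = bp_to_y(rec.pos_bp, track)
            cmds.append(
                LineCmd(
                    tag="mark-line",
                    x1=track.x_px, y1=y, x2=track.x_right_px, y2=y,
                    stroke=color, stroke_w=line_w,
                )
            )
    return cmds


def _glyph_x(track: Track, lane: int, d: float, scale: float) -> float:
    return track.x_right_px + 7.0 * scale + d / 2 + lane * d * 1.15


def draw_glyphs(
    slots: list[GlyphSlot],
    records,
    colors: ColorAssignment,
    shapes: ShapeAssignment,
    track: Track,
    config: PlotConfig,
    scale: float,
) -> list[DrawCmd]:
    """One shape per phenotype-bearing slot, plus its connector line."""
    cmds: list[DrawCmd] = []
    for slot in slots:
        rec = records[slot.record_index]
        if rec.phenotype is None:
            continue
        d = slot.glyph_d_px
        cx = _glyph_x(track, slot.lane, d, scale)
        cy = slot.placed_y_px
        r = d / 2
        fill = colors.color_of(rec.phenotype)
        stroke = _BLACK if config.outline_circle else None
        stroke_w = max(0.8 * scale, 0.6) if config.outline_circle else 0.0
        if slot.lane == 0:
            cmds.append(
                LineCmd(
                    tag="connector",
                    x1=track.x_right_px, y1=slot.anchor_y_px,
                    x2=cx - r, y2=cy,
                    stroke=RGBColor(90, 90, 90), stroke_w=max(0.7 * scale, 0.5),
                )
            )
        shape = shapes.shape_of(rec.ancestry)
        if shape is Shape.CIRCLE:
            cmds.append(
                CircleCmd(tag="glyph", cx=cx, cy=cy, r=r,
                          fill=fill, stroke=stroke, stroke_w=stroke_w)
            )
        elif shape is Shape.SQUARE:
            s = r * 1.772  # square of equal area to the circle
            cmds.append(
                RectCmd(tag="glyph", x=cx - s / 2, y=cy - s / 2, w=s, h=s,
                        fill=fill, stroke=stroke, stroke_w=stroke_w)
            )
        else:
            rr = r * 1.2
            cmds.append(
                PolygonCmd(
                    tag="glyph",
                    points=(
                        (cx, cy - rr),
                        (cx - 0.866 * rr, cy + 0.5 * rr),
                        (cx + 0.866 * rr, cy + 0.5 * rr),
                    ),
                    fill=fill, stroke=stroke, stroke_w=stroke_w,
                )
            )
    return cmds


def draw_annotations(
    slots: list[GlyphSlot],
    records,
    track: Track,
    config: PlotConfig,
    scale: float,
) -> list[DrawCmd]:
    """Note text right of the chromosome, at the spaced y of its record."""
    if not config.include_annotation:
        return []
    cmds: list[DrawCmd] = []
    max_lane = max((s.lane for s in slots), default=0)
    font_px = FONT_PX * scale * (BIG_FONT_FACTOR if config.big_font else 1.0)
    for slot in slots:
        rec = records[slot.record_index]
        if rec.note is None:
            continue
        d = slot.glyph_d_px
        lanes = max_lane + 1 if rec.phenotype is not None else 0
        x = _glyph_x(track, lanes, d, scale)
        cmds.append(
            TextCmd(
                tag="annotation", x=x, y=slot.placed_y_px - font_px * 0.6,
                text=rec.note, font_px=font_px, fill=_BLACK,
            )
        )
    return cmds


def _legend_grid(n: int, width: float, scale: float) -> tuple[int, float]:
    entry_w = 165.0 * scale
    per_row = max(1, int(width // entry_w))
    rows = -(-n // per_row)
    return per_row, rows


def draw_legend(
    colors: ColorAssignment,
    shapes: ShapeAssignment,
    geometry: CanvasGeometry,
    config: PlotConfig,
) -> list[DrawCmd]:
    """Phenotype key across the bottom; a shape key row when ancestry is used."""
    if not colors.legend_order:
        return []
    scale = geometry.scale
    font_px = FONT_PX * scale * (BIG_FONT_FACTOR if config.big_font else 1.0)
    row_h = 26.0 * scale
    entry_w = 165.0 * scale
    per_row, _ = _legend_grid(len(colors.legend_order), geometry.width_px * 0.92, scale)
    x0 = geometry.width_px * 0.04
    # the legend block sits between plot bottom and the lower margin
    y0 = geometry.height_px - 24.0 * scale - geometry.legend_h_px + 8.0 * scale
    cmds: list[DrawCmd] = []
    for i, phen in enumerate(colors.legend_order):
        row, col = divmod(i, per_row)
        x = x0 + col * entry_w
        y = y0 + row * row_h
        sw = 11.0 * scale
        cmds.append(
            RectCmd(tag="legend-swatch", x=x, y=y, w=sw, h=sw,
                    fill=colors.color_of(phen), stroke=_BLACK, stroke_w=0.6 * scale)
        )
        cmds.append(
            TextCmd(tag="legend-label", x=x + sw + 5 * scale, y=y - 1.5 * scale,
                    text=phen, font_px=font_px, fill=_BLACK)
        )
    if shapes.mapping:
        n_rows = -(-len(colors.legend_order) // per_row)
        y = y0 + n_rows * row_h
        for j, (ancestry, shape) in enumerate(shapes.mapping.items()):
            x = x0 + j * entry_w
            r = 5.5 * scale
            cy = y + r
            if shape is Shape.CIRCLE:
                cmds.append(CircleCmd(tag="legend-shape", cx=x + r, cy=cy, r=r,
                                      fill=None, stroke=_BLACK, stroke_w=scale))
            elif shape is Shape.SQUARE:
                cmds.append(RectCmd(tag="legend-shape", x=x, y=cy - r, w=2 * r, h=2 * r,
                                    fill=None, stroke=_BLACK, stroke_w=scale))
            else:
                cmds.append(
                    PolygonCmd(
                        tag="legend-shape",
                        points=((x + r, cy - r), (x, cy + r), (x + 2 * r, cy + r)),
                        fill=None, stroke=_BLACK, stroke_w=scale,
                    )
                )
            cmds.append(
                TextCmd(tag="legend-shape-label", x=x + 2 * r + 5 * scale,
                        y=cy - font_px * 0.55, text=ancestry, font_px=font_px,
                        fill=_BLACK)
            )
    return cmds


def build_scene(
    parsed: ParsedInput,
    genome: GenomeAssembly,
    config: PlotConfig,
) -> tuple[list[DrawCmd], CanvasGeometry, list[str]]:
    """Compose the full figure as drawing commands.

    Returns the command list, the geometry it was planned on, and any
    warnings (zoom exclusions, spacing fallbacks).
    """
    warnings: list[str] = []
    records = validate_against_genome(parsed.records, genome)

    colors = assign_colors(
        parsed.phenotypes,
        config.color_method
        or ("list" if len(parsed.phenotypes) <= 10 else "generator"),
        seed=config.seed,
        groups=parsed.groups if (config.color_method == "group") else None,
    )
    shapes = (
        assign_shapes(parsed.ancestries) if parsed.ancestries else ShapeAssignment({})
    )

    scale = config.dpi / DEFAULT_DPI
    n_phen = len(colors.legend_order)
    legend_rows = 0
    if n_phen:
        _, legend_rows = _legend_grid(n_phen, 1080.0 * 0.92, 1.0)
        if shapes.mapping:
            legend_rows += 1

    geometry = layout_chromosomes(
        genome,
        zoom=config.zoom,
        chrom_only=config.chrom_only,
        records=records,
        small_circle=config.small_circle,
        n_legend_rows=legend_rows,
        title=bool(config.title),
        scale=scale,
    )
    cmds: list[DrawCmd] = []
    if config.title:
        cmds.append(
            TextCmd(
                tag="title", x=geometry.width_px / 2, y=10.0 * scale,
                text=config.title, font_px=16.0 * scale * (BIG_FONT_FACTOR if config.big_font else 1.0),
                anchor="mt", fill=_BLACK,
            )
        )

    # records per displayed track; zoom may exclude some
    per_track: dict[str, list[int]] = {name: [] for name in geometry.tracks}
    for i, rec in enumerate(records):
        track = geometry.tracks.get(rec.chrom)
        if track is None:
            if config.zoom is not None or config.chrom_only:
                continue
            continue
        lo, hi = track.start_bp, track.end_bp
        endpoint = rec.end_bp if rec.is_region else rec.pos_bp
        if endpoint < lo or rec.pos_bp > hi:
            warnings.append(
                f"record at line {rec.line_no} outside the zoom region; excluded"
            )
            continue
        per_track[rec.chrom].append(i)

    for name, track in geometry.tracks.items():
        cdef = genome.chromosome(name)
        cmds.extend(draw_chromosome(track, cdef, genome.bands[name], config, scale))
        indices = per_track[name]
        cmds.extend(draw_position_marks(records, indices, track, config, scale))

        slot_idx = [
            i for i in indices
            if records[i].phenotype is not None
            or (config.include_annotation and records[i].note is not None)
        ]
        if slot_idx:
            slots = make_slots(records, slot_idx, track, geometry.glyph_d_px)
            spaced, notes = SPACING_METHODS[config.spacing](
                slots, track.y_top_px, track.y_bottom_px
            )
            warnings.extend(f"chromosome {name}: {n}" for n in notes)
            cmds.extend(
                draw_glyphs(spaced, records, colors, shapes, track, config, scale)
            )
            cmds.extend(draw_annotations(spaced, records, track, config, scale))

    cmds.extend(draw_legend(colors, shapes, geometry, config))
    return cmds, geometry, warnings


# ---------------------------------------------------------------------------
# backends


def _pil_rgba(color: RGBColor) -> tuple[int, int, int, int]:
    return (color.r, color.g, color.b, round(color.alpha * 255))


def _draw_primitive(draw: ImageDraw.ImageDraw, cmd: DrawCmd, dx: float, dy: float) -> None:
    fill = _pil_rgba(cmd.fill) if cmd.fill else None
    stroke = _pil_rgba(cmd.stroke) if cmd.stroke else None
    width = max(1, round(cmd.stroke_w))
    if isinstance(cmd, LineCmd):
        draw.line(
            [(cmd.x1 - dx, cmd.y1 - dy), (cmd.x2 - dx, cmd.y2 - dy)],
            fill=stroke, width=width,
        )
    elif isinstance(cmd, RectCmd):
        draw.rectangle(
            [cmd.x - dx, cmd.y - dy, cmd.x + cmd.w - dx, cmd.y + cmd.h - dy],
            fill=fill, outline=stroke, width=width if stroke else 0,
        )
    elif isinstance(cmd, RoundedRectCmd):
        draw.rounded_rectangle(
            [cmd.x - dx, cmd.y - dy, cmd.x + cmd.w - dx, cmd.y + cmd.h - dy],
            radius=cmd.radius, fill=fill, outline=stroke,
            width=width if stroke else 0,
        )
    elif isinstance(cmd, CircleCmd):
        draw.ellipse(
            [cmd.cx - cmd.r - dx, cmd.cy - cmd.r - dy,
             cmd.cx + cmd.r - dx, cmd.cy + cmd.r - dy],
            fill=fill, outline=stroke, width=width if stroke else 0,
        )
    elif isinstance(cmd, PolygonCmd):
        draw.polygon(
            [(px - dx, py - dy) for px, py in cmd.points],
            fill=fill, outline=stroke, width=width if stroke else 0,
        )
    elif isinstance(cmd, TextCmd):
        font = ImageFont.load_default(size=cmd.font_px)
        x = cmd.x - dx
        if cmd.anchor == "mt":
            x -= draw.textlength(cmd.text, font=font) / 2
        draw.text((x, cmd.y - dy), cmd.text, fill=fill or (0, 0, 0, 255), font=font)


def _rasterize(cmds: list[DrawCmd], geometry: CanvasGeometry, dpi: int) -> bytes:
    W, H = round(geometry.width_px), round(geometry.height_px)
    img = Image.new("RGB", (W, H), (255, 255, 255))
    opaque = ImageDraw.Draw(img)
    for cmd in cmds:
        translucent = (cmd.fill and cmd.fill.alpha < 1.0) or (
            cmd.stroke and cmd.stroke.alpha < 1.0
        )
        if not translucent:
            _draw_primitive(opaque, cmd, 0.0, 0.0)
            continue
        # alpha-composite within the primitive's bounding box so stacked
        # translucent marks darken where they overlap
        x0, y0, x1, y1 = cmd.bbox()
        bx0, by0 = max(0, int(x0) - 1), max(0, int(y0) - 1)
        bx1, by1 = min(W, int(x1) + 2), min(H, int(y1) + 2)
        if bx0 >= bx1 or by0 >= by1:
            continue
        base = img.crop((bx0, by0, bx1, by1)).convert("RGBA")
        overlay = Image.new("RGBA", base.size, (0, 0, 0, 0))
        _draw_primitive(ImageDraw.Draw(overlay), cmd, float(bx0), float(by0))
        img.paste(Image.alpha_composite(base, overlay).convert("RGB"), (bx0, by0))
    buf = io.BytesIO()
    img.save(buf, format="PNG", dpi=(dpi, dpi))
    return buf.getvalue()


def _svg_color(color: RGBColor | None) -> str:
    return color.hex if color else "none"


def _svg_cmd(cmd: DrawCmd) -> str:
    common = f'fill="{_svg_color(cmd.fill)}"'
    if cmd.fill and cmd.fill.alpha < 1.0:
        common += f' fill-opacity="{cmd.fill.alpha:g}"'
    if cmd.stroke:
        common += f' stroke="{cmd.stroke.hex}" stroke-width="{cmd.stroke_w:.2f}"'
        if cmd.stroke.alpha < 1.0:
            common += f' stroke-opacity="{cmd.stroke.alpha:g}"'
    if isinstance(cmd, LineCmd):
        return (
            f'<line x1="{cmd.x1:.2f}" y1="{cmd.y1:.2f}" x2="{cmd.x2:.2f}" '
            f'y2="{cmd.y2:.2f}" {common}/>'
        )
    if isinstance(cmd, RoundedRectCmd):
        return (
            f'<rect x="{cmd.x:.2f}" y="{cmd.y:.2f}" width="{cmd.w:.2f}" '
            f'height="{cmd.h:.2f}" rx="{cmd.radius:.2f}" {common}/>'
        )
    if isinstance(cmd, RectCmd):
        return (
            f'<rect x="{cmd.x:.2f}" y="{cmd.y:.2f}" width="{cmd.w:.2f}" '
            f'height="{cmd.h:.2f}" {common}/>'
        )
    if isinstance(cmd, CircleCmd):
        return f'<circle cx="{cmd.cx:.2f}" cy="{cmd.cy:.2f}" r="{cmd.r:.2f}" {common}/>'
    if isinstance(cmd, PolygonCmd):
        pts = " ".join(f"{px:.2f},{py:.2f}" for px, py in cmd.points)
        return f'<polygon points="{pts}" {common}/>'
    if isinstance(cmd, TextCmd):
        anchor = "middle" if cmd.anchor == "mt" else "start"
        fill = cmd.fill.hex if cmd.fill else "#000000"
        return (
            f'<text x="{cmd.x:.2f}" y="{cmd.y + cmd.font_px:.2f}" '
            f'font-size="{cmd.font_px:.1f}" text-anchor="{anchor}" '
            f'font-family="Helvetica, Arial, sans-serif" fill="{fill}">'
            f"{saxutils.escape(cmd.text)}</text>"
        )
    raise TypeError(f"unknown drawing command {type(cmd).__name__}")


def _to_svg(cmds: list[DrawCmd], geometry: CanvasGeometry) -> bytes:
    W, H = geometry.width_px, geometry.height_px
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{W:.0f}" height="{H:.0f}" viewBox="0 0 {W:.0f} {H:.0f}">',
        f'<rect x="0" y="0" width="{W:.0f}" height="{H:.0f}" fill="#ffffff"/>',
    ]
    parts.extend(_svg_cmd(c) for c in cmds)
    parts.append("</svg>")
    return "\n".join(parts).encode("utf-8")


def render(
    parsed: ParsedInput, genome: GenomeAssembly, config: PlotConfig | None = None
) -> tuple[RenderedImage, list[str]]:
    """Render the full figure; returns the image and any warnings."""
    config = config or PlotConfig()
    cmds, geometry, warnings = build_scene(parsed, genome, config)
    if config.out_format == "png":
        payload = _rasterize(cmds, geometry, config.dpi)
    else:
        payload = _to_svg(cmds, geometry)
    return (
        RenderedImage(
            payload=payload,
            width_px=round(geometry.width_px),
            height_px=round(geometry.height_px),
            dpi=config.dpi,
            format=config.out_format,
        ),
        warnings,
    )
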