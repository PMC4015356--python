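"""Resolution-independent drawing commands.

The renderer first composes the whole figure as a flat list of primitive
commands in canvas coordinates, each carrying a semantic ``tag`` (band,
mark, glyph, connector, annotation, legend-swatch, ...). Backends then
rasterize the list with Pillow or serialize it as SVG. Keeping the scene
explicit makes the figure inspectable: tests count commands instead of
reading pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .colors import RGBColor

__all__ = [
    "DrawCmd",
    "LineCmd",
    "RectCmd",
    "RoundedRectCmd",
    "CircleCmd",
    "PolygonCmd",
    "TextCmd",
]


@dataclass(frozen=True, slots=True, kw_only=True)
class DrawCmd:
    tag: str
    fill: RGBColor | None = None
    stroke: RGBColor | None = None
    stroke_w: float = 1.0

    def bbox(self) -> tuple[float, float, float, float]:  # (x0, y0, x1, y1)
        raise NotImplementedError


@dataclass(frozen=True, slots=True, kw_only=True)
class LineCmd(DrawCmd):
    x1: float
    y1: float
    x2: float
    y2: float

    def bbox(self):
        pad = self.stroke_w
        return (
            min(self.x1, self.x2) - pad,
            min(self.y1, self.y2) - pad,
            max(self.x1, self.x2) + pad,
            max(self.y1, self.y2) + pad,
        )


@dataclass(frozen=True, slots=True, kw_only=True)
class RectCmd(DrawCmd):
    x: float
    y: float
    w: float
    h: float

    def bbox(self):
        pad = self.stroke_w
        return (self.x - pad, self.y - pad, self.x + self.w + pad, self.y + self.h + pad)


@dataclass(frozen=True, slots=True, kw_only=True)
class RoundedRectCmd(DrawCmd):
    x: float
    y: float
    w: float
    h: float
    radius: float = 0.0

    def bbox(self):
        pad = self.stroke_w
        return (self.x - pad, self.y - pad, self.x + self.w + pad, self.y + self.h + pad)


@dataclass(frozen=True, slots=True, kw_only=True)
class CircleCmd(DrawCmd):
    cx: float
    cy: float
    r: float

    def bbox(self):
        pad = self.r + self.stroke_w
        return (self.cx - pad, self.cy - pad, self.cx + pad, self.cy + pad)


@dataclass(frozen=True, slots=True, kw_only=True)
class PolygonCmd(DrawCmd):
    points: tuple[tuple[float, float], ...] = field(default=())

    def bbox(self):
        xs = [p[0] for p in self.points]
        ys = [p[1] for p in self.points]
        pad = self.stroke_w
        return (min(xs) - pad, min(ys) - pad, max(xs) + pad, max(ys) + pad)


@dataclass(frozen=True, slots=True, kw_only=True)
class TextCmd(DrawCmd):
    x: float
    y: float                 # top-left anchor
    text: str = ""
    font_px: float = 11.0
    anchor: str = "lt"       # lt: left-top, mt: middle-top

    def bbox(self):
        w = 0.62 * self.font_px * len(self.text)
        x0 = self.x - w / 2 if self.anchor == "mt" else self.x
        return (x0, self.y, x0 + w, self.y + self.font_px * 1.25)


def scene_bbox(commands: Sequence[DrawCmd]) -> tuple[float, float, float, float]:
    """Union of all command bounding boxes."""
    boxes = [c.bbox() for c in commands]
    return (
        min(b[0] for b in boxes),
        min(b[1] for b in boxes),
        max(b[2] for b in boxes),
        max(b[3] for b in boxes),
    )
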