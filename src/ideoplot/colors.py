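"""Color assignment for phenotypes, shapes for ancestries, mark colors.

Five phenotype coloring methods are offered:

* ``list`` — a fixed ten-entry palette of well-separated, colorblind-aware
  colors; the right choice for ten or fewer phenotypes.
* ``generator`` — hues evenly spaced around the HSV wheel (360/n degrees
  apart) at fixed saturation/value, for any number of phenotypes.
* ``web`` — a seeded draw without replacement from the 216 web-safe colors
  (every RGB channel a multiple of 51).
* ``random`` — seeded independent uniform RGB draws, with no guarantee of
  perceptual separation.
* ``group`` — phenotypes sharing a GROUP identifier take one base hue and a
  lightness gradient within it, so groups read as color families.

All stochastic choices flow from one integer seed (default 7) and are
fully reproducible.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import UsageError

__all__ = [
    "RGBColor",
    "Shape",
    "ColorAssignment",
    "ShapeAssignment",
    "DEFAULT_SEED",
    "LIST_PALETTE",
    "POSCOLOR_TABLE",
    "list_palette",
    "generator_palette",
    "web_safe_palette",
    "assign_colors",
    "assign_shapes",
    "poscolor_lookup",
]

#: Global default RNG seed.
DEFAULT_SEED = 7

#: HSV saturation/value used by the generator method.
GENERATOR_S = 0.78
GENERATOR_V = 0.90


@dataclass(frozen=True, slots=True)
class RGBColor:
    """An 8-bit RGB color with an optional alpha fraction."""

    r: int
    g: int
    b: int
    alpha: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"channel {name}={v} outside 0-255")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha {self.alpha} outside 0-1")

    @property
    def rgb(self) -> tuple[int, int, int]:
        return (self.r, self.g, self.b)

    @property
    def hex(self) -> str:
        return f"#{self.r:02x}{self.g:02x}{self.b:02x}"

    def with_alpha(self, alpha: float) -> "RGBColor":
        return RGBColor(self.r, self.g, self.b, alpha)

    def hue_deg(self) -> float:
        h, _, _ = colorsys.rgb_to_hsv(self.r / 255, self.g / 255, self.b / 255)
        return h * 360.0


class Shape(str, Enum):
    CIRCLE = "circle"
    SQUARE = "square"
    TRIANGLE = "triangle"


#: Shape order for successive ancestry groups; groups beyond the third fall
#: back to the circle.
SHAPE_ORDER = (Shape.CIRCLE, Shape.SQUARE, Shape.TRIANGLE)

#: The fixed palette behind the ``list`` method: ten well-separated,
#: colorblind-aware colors (documented constants of this package).
LIST_PALETTE: tuple[RGBColor, ...] = (
    RGBColor(230, 25, 75),    # red
    RGBColor(0, 110, 230),    # blue
    RGBColor(60, 180, 75),    # green
    RGBColor(245, 130, 48),   # orange
    RGBColor(145, 30, 180),   # purple
    RGBColor(70, 240, 240),   # cyan
    RGBColor(240, 190, 20),   # yellow
    RGBColor(240, 50, 230),   # magenta
    RGBColor(128, 105, 40),   # olive-brown
    RGBColor(0, 0, 0),        # black
)

#: Transverse-mark colors keyed by the POSCOLOR integer codes 0-7.
POSCOLOR_TABLE: dict[int, RGBColor] = {
    0: RGBColor(0, 0, 0),        # black (default line color)
    1: RGBColor(220, 30, 30),    # red
    2: RGBColor(30, 60, 220),    # blue
    3: RGBColor(20, 150, 50),    # green
    4: RGBColor(245, 140, 20),   # orange
    5: RGBColor(140, 40, 180),   # purple
    6: RGBColor(140, 85, 35),    # brown
    7: RGBColor(230, 40, 200),   # magenta
}


@dataclass
class ColorAssignment:
    """Phenotype -> color map plus the legend order."""

    method: str
    mapping: dict[str, RGBColor]
    legend_order: list[str] = field(default_factory=list)

    def color_of(self, phenotype: str) -> RGBColor:
        return self.mapping[phenotype]


@dataclass
class ShapeAssignment:
    """Ancestry -> glyph shape map; unknown/absent ancestry means circle."""

    mapping: dict[str, Shape]
    overflow_shape: Shape = Shape.CIRCLE

    def shape_of(self, ancestry: str | None) -> Shape:
        if ancestry is None:
            return Shape.CIRCLE
        return self.mapping.get(ancestry, self.overflow_shape)


def list_palette(n: int) -> list[RGBColor]:
    """First ``n`` entries of the fixed ten-color list (n <= 10)."""
    if n < 1:
        raise ValueError(f"need at least one color, got n={n}")
    if n > len(LIST_PALETTE):
        raise UsageError(
            f"the list color method offers at most {len(LIST_PALETTE)} colors "
            f"({n} requested); use the generator method for more phenotypes"
        )
    return list(LIST_PALETTE[:n])


def generator_palette(n: int) -> list[RGBColor]:
    """``n`` colors with hues evenly spaced 360/n degrees apart.

    Saturation and value are fixed, so hue separation is the sole
    discriminator; colors are pairwise distinct for any practical n.
    """
    if n < 1:
        raise ValueError(f"need at least one color, got n={n}")
    palette = []
    for i in range(n):
        h = i / n
        r, g, b = colorsys.hsv_to_rgb(h, GENERATOR_S, GENERATOR_V)
        palette.append(RGBColor(round(r * 255), round(g * 255), round(b * 255)))
    return palette


def web_safe_palette() -> list[RGBColor]:
    """All 216 web-safe colors: each channel in {0, 51, 102, 153, 204, 255}."""
    levels = (0, 51, 102, 153, 204, 255)
    return [RGBColor(r, g, b) for r in levels for g in levels for b in levels]


def _group_gradient(base: RGBColor, k: int) -> list[RGBColor]:
    """k colors of the base hue with strictly increasing lightness."""
    h, _, s = colorsys.rgb_to_hls(base.r / 255, base.g / 255, base.b / 255)
    if k == 1:
        lightnesses = [0.5]
    else:
        lightnesses = list(np.linspace(0.3, 0.75, k))
    out = []
    for light in lightnesses:
        r, g, b = colorsys.hls_to_rgb(h, light, max(s, 0.5))
        out.append(RGBColor(round(r * 255), round(g * 255), round(b * 255)))
    return out


def assign_colors(
    phenotypes: Sequence[str],
    method: str = "list",
    seed: int = DEFAULT_SEED,
    groups: Mapping[str, str] | None = None,
) -> ColorAssignment:
    """Assign one color per distinct phenotype, preserving legend order.

    ``phenotypes`` must be the distinct labels in first-appearance order;
    that order becomes the legend order. ``groups`` (phenotype -> group
    label) is required for the ``group`` method.
    """
    labels = list(dict.fromkeys(phenotypes))
    n = len(labels)
    if n == 0:
        return ColorAssignment(method, {}, [])

    if method == "list":
        palette = list_palette(n)
    elif method == "generator":
        palette = generator_palette(n)
    elif method == "web":
        lattice = web_safe_palette()
        if n > len(lattice):
            raise UsageError(f"web method offers at most {len(lattice)} colors")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(lattice))
        palette = [lattice[i] for i in order[:n]]
    elif method == "random":
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, 256, size=(n, 3))
        palette = [RGBColor(int(r), int(g), int(b)) for r, g, b in draws]
    elif method == "group":
        if groups is None:
            raise UsageError("group color method requires a GROUP column")
        missing = [p for p in labels if p not in groups]
        if missing:
            raise UsageError(
                f"group color method: phenotypes without a group: {missing}"
            )
        group_order = list(dict.fromkeys(groups[p] for p in labels))
        base_hues = generator_palette(len(group_order))
        members = {g: [p for p in labels if groups[p] == g] for g in group_order}
        mapping: dict[str, RGBColor] = {}
        for g, base in zip(group_order, base_hues):
            for phen, color in zip(members[g], _group_gradient(base, len(members[g]))):
                mapping[phen] = color
        return ColorAssignment(method, mapping, labels)
    else:
        raise UsageError(
            f"unknown color method {method!r}; "
            "choose random, web, generator, group or list"
        )
    return ColorAssignment(method, dict(zip(labels, palette)), labels)


def assign_shapes(ancestries: Iterable[str]) -> ShapeAssignment:
    """Map ancestry labels (first-appearance order) onto glyph shapes.

    The first three distinct groups get circle, square and triangle; every
    later group falls back to the circle, so at most three shapes are ever
    in play.
    """
    mapping: dict[str, Shape] = {}
    for label in dict.fromkeys(ancestries):
        idx = len(mapping)
        mapping[label] = SHAPE_ORDER[idx] if idx < len(SHAPE_ORDER) else Shape.CIRCLE
    return ShapeAssignment(mapping)


def poscolor_lookup(code: int) -> RGBColor:
    """Color for a POSCOLOR code (0-7); 0 is the default black."""
    try:
        return POSCOLOR_TABLE[code]
    except KeyError:
        raise UsageError(f"POSCOLOR code must be an integer 0-7, got {code}") from None
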