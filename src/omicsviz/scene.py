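"""Resolution-independent scene graph shared by all layouts.

A :class:`Scene` is an ordered list of :class:`Glyph` primitives in an
abstract canvas coordinate system (origin top-left, y increasing downward).
Layout modules produce scenes; the :mod:`omicsviz.render` module consumes
them.  Angles on arc sectors follow the mathematical convention (degrees,
counterclockwise from 3 o'clock) so that 90 degrees is 12 o'clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = ["Glyph", "Scene", "vstack_glyphs"]

#: estimated glyph width per character, as a fraction of the font size;
#: the renderer owns real font metrics, layouts reserve space with this.
CHAR_WIDTH_FACTOR = 0.6


@dataclass(frozen=True)
class Glyph:
    """One drawing primitive.

    ``kind`` is one of ``rect``, ``rect_outline``, ``point``, ``polygon``,
    ``segment``, ``arc_sector``, ``text``.  ``coords`` depends on the kind:

    - rect / rect_outline: (x, y, width, height)
    - point: (cx, cy, radius)
    - polygon: flattened vertices (x1, y1, x2, y2, ...)
    - segment: (x1, y1, x2, y2)
    - arc_sector: (cx, cy, r_inner, r_outer, angle_start, angle_end)
    - text: (x, y) anchor position (y is the baseline)

    ``layer`` totally orders overlapping glyphs (lower drawn first);
    ``tag`` is a free-form role label ("heatmap:mrna", "legend:ramp", ...)
    used by tests and glyph accounting, never by the renderer.
    """

    kind: str
    coords: tuple
    color: str | None = None
    stroke_width: float = 1.0
    text: str | None = None
    anchor: str = "start"  # start | middle | end
    font_size: float = 10.0
    rotation: float = 0.0  # degrees, clockwise on screen, about the anchor
    layer: int = 0
    tag: str = ""

    def translated(self, dx: float, dy: float) -> "Glyph":
        c = self.coords
        if self.kind in ("rect", "rect_outline"):
            nc = (c[0] + dx, c[1] + dy, c[2], c[3])
        elif self.kind == "point":
            nc = (c[0] + dx, c[1] + dy, c[2])
        elif self.kind == "polygon":
            nc = tuple(v + (dx if i % 2 == 0 else dy) for i, v in enumerate(c))
        elif self.kind == "segment":
            nc = (c[0] + dx, c[1] + dy, c[2] + dx, c[3] + dy)
        elif self.kind == "arc_sector":
            nc = (c[0] + dx, c[1] + dy) + tuple(c[2:])
        elif self.kind == "text":
            nc = (c[0] + dx, c[1] + dy)
        else:  # pragma: no cover - construction validates kinds
            raise ValueError(f"unknown glyph kind {self.kind!r}")
        return replace(self, coords=nc)

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax); conservative for arcs and text."""
        c = self.coords
        if self.kind in ("rect", "rect_outline"):
            return (c[0], c[1], c[0] + c[2], c[1] + c[3])
        if self.kind == "point":
            return (c[0] - c[2], c[1] - c[2], c[0] + c[2], c[1] + c[2])
        if self.kind == "polygon":
            xs, ys = c[0::2], c[1::2]
            return (min(xs), min(ys), max(xs), max(ys))
        if self.kind == "segment":
            return (min(c[0], c[2]), min(c[1], c[3]),
                    max(c[0], c[2]), max(c[1], c[3]))
        if self.kind == "arc_sector":
            cx, cy, _, r_out = c[0], c[1], c[2], c[3]
            return (cx - r_out, cy - r_out, cx + r_out, cy + r_out)
        if self.kind == "text":
            return self._text_box()
        raise ValueError(f"unknown glyph kind {self.kind!r}")

    def _text_box(self) -> tuple[float, float, float, float]:
        x, y = self.coords
        w = CHAR_WIDTH_FACTOR * self.font_size * len(self.text or "")
        h = self.font_size
        if self.anchor == "middle":
            x0 = x - w / 2
        elif self.anchor == "end":
            x0 = x - w
        else:
            x0 = x
        corners = [(x0, y - h), (x0 + w, y - h), (x0, y), (x0 + w, y)]
        if self.rotation:
            a = math.radians(self.rotation)
            ca, sa = math.cos(a), math.sin(a)
            corners = [
                (x + (px - x) * ca - (py - y) * sa,
                 y + (px - x) * sa + (py - y) * ca)
                for px, py in corners
            ]
        xs = [p[0] for p in corners]
        ys = [p[1] for p in corners]
        return (min(xs), min(ys), max(xs), max(ys))


@dataclass
class Scene:
    """A canvas of given width/height holding an ordered glyph list."""

    width: float
    height: float
    glyphs: list[Glyph] = field(default_factory=list)

    def add(self, *glyphs: Glyph) -> None:
        self.glyphs.extend(glyphs)

    def count(self, tag_prefix: str | None = None, kind: str | None = None) -> int:
        n = 0
        for g in self.glyphs:
            if tag_prefix is not None and not g.tag.startswith(tag_prefix):
                continue
            if kind is not None and g.kind != kind:
                continue
            n += 1
        return n

    def select(self, tag_prefix: str) -> list[Glyph]:
        return [g for g in self.glyphs if g.tag.startswith(tag_prefix)]

    def in_bounds(self, tol: float = 1e-6) -> bool:
        for g in self.glyphs:
            x0, y0, x1, y1 = g.bounding_box()
            if x0 < -tol or y0 < -tol or x1 > self.width + tol or y1 > self.height + tol:
                return False
        return True

    def out_of_bounds_glyphs(self, tol: float = 1e-6) -> list[Glyph]:
        bad = []
        for g in self.glyphs:
            x0, y0, x1, y1 = g.bounding_box()
            if x0 < -tol or y0 < -tol or x1 > self.width + tol or y1 > self.height + tol:
                bad.append(g)
        return bad


def vstack_glyphs(scene: Scene, glyphs: list[Glyph], pad: float = 10.0) -> Scene:
    """Append a glyph block (e.g. a legend) below a scene.

    The block is translated so its bounding box starts ``pad`` below the
    scene and at the scene's left margin; the scene grows to fit.
    """
    if not glyphs:
        return scene
    boxes = [g.bounding_box() for g in glyphs]
    x0 = min(b[0] for b in boxes)
    y0 = min(b[1] for b in boxes)
    x1 = max(b[2] for b in boxes)
    y1 = max(b[3] for b in boxes)
    dx, dy = pad - x0, scene.height + pad - y0
    moved = [g.translated(dx, dy) for g in glyphs]
    return Scene(
        width=max(scene.width, x1 - x0 + 2 * pad),
        height=scene.height + pad + (y1 - y0) + pad,
        glyphs=list(scene.glyphs) + moved,
    )
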