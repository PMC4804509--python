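"""Scene rendering: SVG 1.1 text output and PNG rasterization.

SVG output is fully deterministic — stable element order (layer, then
insertion order), fixed attribute order, all numbers rounded to 3
decimals — so byte-identical scenes always serialize to byte-identical
files.  PNG goes through Pillow; arc sectors are approximated with
polygons at >= 32 segments per full circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from PIL import Image, ImageDraw, ImageFont

from .scene import Glyph, Scene

__all__ = ["RenderOptions", "render_scene", "scene_to_svg", "compose_panels"]

_KNOWN_KINDS = {"rect", "rect_outline", "point", "polygon", "segment",
                "arc_sector", "text"}


@dataclass(frozen=True)
class RenderOptions:
    format: str = "svg"  # svg | png
    pixel_scale: float = 1.0
    background: str = "#ffffff"
    font_family: str = "sans-serif"

    def __post_init__(self) -> None:
        if self.format not in ("svg", "png"):
            raise ValueError(f"unknown format {self.format!r}")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")


def _f(x: float) -> str:
    """Stable 3-decimal number formatting (no trailing-zero stripping)."""
    s = f"{x:.3f}"
    return "0.000" if s == "-0.000" else s


def _sorted_glyphs(scene: Scene) -> list[Glyph]:
    return [g for _, _, g in sorted(
        (g.layer, i, g) for i, g in enumerate(scene.glyphs)
    )]


def _arc_endpoints(c) -> tuple[tuple[float, float], ...]:
    cx, cy, r_in, r_out, a0, a1 = c

    def pt(r, a):
        ar = math.radians(a)
        return (cx + r * math.cos(ar), cy - r * math.sin(ar))

    return pt(r_out, a0), pt(r_out, a1), pt(r_in, a1), pt(r_in, a0)


def _svg_element(g: Glyph, font_family: str) -> str:
    c = g.coords
    fill = g.color or "none"
    if g.kind == "rect":
        return (f'<rect x="{_f(c[0])}" y="{_f(c[1])}" width="{_f(c[2])}" '
                f'height="{_f(c[3])}" fill="{fill}"/>')
    if g.kind == "rect_outline":
        return (f'<rect x="{_f(c[0])}" y="{_f(c[1])}" width="{_f(c[2])}" '
                f'height="{_f(c[3])}" fill="none" stroke="{fill}" '
                f'stroke-width="{_f(g.stroke_width)}"/>')
    if g.kind == "point":
        return (f'<circle cx="{_f(c[0])}" cy="{_f(c[1])}" r="{_f(c[2])}" '
                f'fill="{fill}"/>')
    if g.kind == "polygon":
        pts = " ".join(f"{_f(c[i])},{_f(c[i + 1])}" for i in range(0, len(c), 2))
        return f'<polygon points="{pts}" fill="{fill}"/>'
    if g.kind == "segment":
        return (f'<line x1="{_f(c[0])}" y1="{_f(c[1])}" x2="{_f(c[2])}" '
                f'y2="{_f(c[3])}" stroke="{fill}" '
                f'stroke-width="{_f(g.stroke_width)}"/>')
    if g.kind == "arc_sector":
        cx, cy, r_in, r_out, a0, a1 = c
        p0, p1, p2, p3 = _arc_endpoints(c)
        sweep = 1 if a1 < a0 else 0  # decreasing math angle = clockwise on screen
        large = 1 if abs(a1 - a0) > 180 else 0
        d = (f"M {_f(p0[0])} {_f(p0[1])} "
             f"A {_f(r_out)} {_f(r_out)} 0 {large} {sweep} {_f(p1[0])} {_f(p1[1])} "
             f"L {_f(p2[0])} {_f(p2[1])} "
             f"A {_f(r_in)} {_f(r_in)} 0 {large} {1 - sweep} {_f(p3[0])} {_f(p3[1])} Z")
        return f'<path d="{d}" fill="{fill}"/>'
    if g.kind == "text":
        anchor = {"start": "start", "middle": "middle", "end": "end"}[g.anchor]
        rot = (f' transform="rotate({_f(g.rotation)} {_f(c[0])} {_f(c[1])})"'
               if g.rotation else "")
        payload = (g.text or "").replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        return (f'<text x="{_f(c[0])}" y="{_f(c[1])}" '
                f'font-family="{font_family}" font-size="{_f(g.font_size)}" '
                f'text-anchor="{anchor}" fill="{g.color or "#000000"}"{rot}>'
                f"{payload}</text>")
    raise ValueError(f"unknown glyph kind {g.kind!r}")


def scene_to_svg(scene: Scene, options: RenderOptions | None = None) -> str:
    options = options or RenderOptions()
    w = scene.width * options.pixel_scale
    h = scene.height * options.pixel_scale
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(w)}" height="{_f(h)}" '
        f'viewBox="0 0 {_f(scene.width)} {_f(scene.height)}">',
        f'<rect x="0.000" y="0.000" width="{_f(scene.width)}" '
        f'height="{_f(scene.height)}" fill="{options.background}"/>',
    ]
    for g in _sorted_glyphs(scene):
        lines.append(_svg_element(g, options.font_family))
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def _arc_polygon(c, min_segments_per_circle: int = 32) -> list[tuple[float, float]]:
    cx, cy, r_in, r_out, a0, a1 = c
    span = abs(a1 - a0)
    n = max(2, int(math.ceil(min_segments_per_circle * span / 360.0)))
    outer = []
    inner = []
    for i in range(n + 1):
        a = a0 + (a1 - a0) * i / n
        ar = math.radians(a)
        outer.append((cx + r_out * math.cos(ar), cy - r_out * math.sin(ar)))
        inner.append((cx + r_in * math.cos(ar), cy - r_in * math.sin(ar)))
    return outer + inner[::-1]


def _render_png(scene: Scene, options: RenderOptions, path: Path) -> None:
    s = options.pixel_scale
    size = (max(1, round(scene.width * s)), max(1, round(scene.height * s)))
    img = Image.new("RGB", size, options.background)
    draw = ImageDraw.Draw(img)
    font = ImageFont.load_default()
    for g in _sorted_glyphs(scene):
        c = tuple(v * s for v in g.coords) if g.kind != "text" else g.coords
        if g.kind == "rect":
            draw.rectangle([c[0], c[1], c[0] + c[2], c[1] + c[3]], fill=g.color)
        elif g.kind == "rect_outline":
            draw.rectangle([c[0], c[1], c[0] + c[2], c[1] + c[3]],
                           outline=g.color, width=max(1, round(g.stroke_width * s)))
        elif g.kind == "point":
            draw.ellipse([c[0] - c[2], c[1] - c[2], c[0] + c[2], c[1] + c[2]],
                         fill=g.color)
        elif g.kind == "polygon":
            draw.polygon([(c[i], c[i + 1]) for i in range(0, len(c), 2)], fill=g.color)
        elif g.kind == "segment":
            draw.line([c[0], c[1], c[2], c[3]], fill=g.color,
                      width=max(1, round(g.stroke_width * s)))
        elif g.kind == "arc_sector":
            sc = (c[0], c[1], c[2], c[3], g.coords[4], g.coords[5])
            draw.polygon(_arc_polygon(sc), fill=g.color)
        elif g.kind == "text":
            x, y = g.coords[0] * s, g.coords[1] * s
            txt = g.text or ""
            bbox = draw.textbbox((0, 0), txt, font=font)
            tw = bbox[2] - bbox[0]
            if g.anchor == "middle":
                x -= tw / 2
            elif g.anchor == "end":
                x -= tw
            if g.rotation:
                tile = Image.new("RGBA", (bbox[2] + 2, bbox[3] + 2), (0, 0, 0, 0))
                ImageDraw.Draw(tile).text((0, 0), txt, font=font, fill=g.color)
                tile = tile.rotate(-g.rotation, expand=True)
                img.paste(tile, (round(x), round(y)), tile)
            else:
                draw.text((x, y - bbox[3]), txt, font=font, fill=g.color)
        else:
            raise ValueError(f"unknown glyph kind {g.kind!r}")
    img.save(path, format="PNG")


def render_scene(scene: Scene, options: RenderOptions, output_path: str | Path) -> Path:
    """Write the scene to ``output_path`` in the requested format.

    The scene is never mutated; SVG output is byte-deterministic.
    """
    path = Path(output_path)
    for g in scene.glyphs:
        if g.kind not in _KNOWN_KINDS:
            raise ValueError(f"unknown glyph kind {g.kind!r}")
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    if options.format == "svg":
        path.write_text(scene_to_svg(scene, options), encoding="utf-8")
    else:
        _render_png(scene, options, path)
    return path


def compose_panels(scenes: list[Scene], grid: tuple[int, int]) -> Scene:
    """Place scenes into a rows x cols grid of uniform cells.

    Each scene keeps its internal geometry (pure translation into its
    cell, centered); cells are sized to the largest scene.
    """
    rows, cols = grid
    if not scenes:
        raise ValueError("compose_panels needs at least one scene")
    if rows * cols < len(scenes):
        raise ValueError(
            f"grid {rows}x{cols} has fewer cells than scenes ({len(scenes)})"
        )
    cell_w = max(s.width for s in scenes)
    cell_h = max(s.height for s in scenes)
    out = Scene(width=cols * cell_w, height=rows * cell_h)
    for i, s in enumerate(scenes):
        r, c = divmod(i, cols)
        dx = c * cell_w + (cell_w - s.width) / 2.0
        dy = r * cell_h + (cell_h - s.height) / 2.0
        out.glyphs.extend(g.translated(dx, dy) for g in s.glyphs)
    return out
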