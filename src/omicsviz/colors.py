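"""Color scales binding omics values to colors.

Three bindings cover every track type: a diverging continuous scale for
expression heatmaps (default "BlueWhiteRed" over [-3, 3], the conventional
bounds for log-ratio expression), an ordered categorical palette for
methylation-status outlines/bars, and a binary loss/neutral/gain palette
for copy-number points.  Colors serialize as lowercase "#rrggbb".
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ContinuousScale",
    "CategoryPalette",
    "BinaryPalette",
    "map_continuous",
    "map_category",
    "map_binary",
    "DEFAULT_CATEGORY_COLORS",
]

# tab10-style cycle used for clinical-feature rectangles and category codes
DEFAULT_CATEGORY_COLORS = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)

# named diverging ramps: ordered anchor colors, linearly interpolated
_RAMPS: dict[str, tuple[tuple[int, int, int], ...]] = {
    "BlueWhiteRed": ((0, 0, 255), (255, 255, 255), (255, 0, 0)),
    "GreenBlackRed": ((0, 255, 0), (0, 0, 0), (255, 0, 0)),
}


def _hex(rgb: tuple[int, int, int]) -> str:
    return "#%02x%02x%02x" % rgb


@dataclass(frozen=True)
class ContinuousScale:
    """Diverging scale clamped to [vmin, vmax]; midpoint is neutral."""

    name: str = "BlueWhiteRed"
    vmin: float = -3.0
    vmax: float = 3.0
    missing_color: str = "#bdbdbd"

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError(f"vmin ({self.vmin}) must be < vmax ({self.vmax})")
        if self.name not in _RAMPS:
            raise ValueError(
                f"unknown ramp {self.name!r}; known: {sorted(_RAMPS)}"
            )

    def interp_param(self, value: float) -> float:
        """Clamped position of ``value`` on the ramp, in [0, 1]."""
        t = (value - self.vmin) / (self.vmax - self.vmin)
        return min(1.0, max(0.0, t))


@dataclass(frozen=True)
class CategoryPalette:
    """Ordered code -> color map; ``outline_mode`` marks outline use."""

    colors: tuple[str, ...] = ("#d95f02", "#7570b3")
    outline_mode: bool = False
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.colors)) != len(self.colors):
            raise ValueError("category palette colors must be distinct")

    def color(self, code: int) -> str:
        if not 0 <= code < len(self.colors):
            raise KeyError(
                f"category code {code} outside palette of {len(self.colors)} colors"
            )
        return self.colors[code]


@dataclass(frozen=True)
class BinaryPalette:
    """Loss/neutral/gain colors; neutral is not drawn."""

    color_loss: str = "#2166ac"
    color_gain: str = "#b2182b"

    def __post_init__(self) -> None:
        if self.color_loss == self.color_gain:
            raise ValueError("loss and gain colors must be distinct")


def map_continuous(value: float | None, scale: ContinuousScale) -> str:
    """Map a value to its ramp color; clamps out-of-range, None -> missing."""
    if value is None or value != value:  # None or NaN
        return scale.missing_color
    stops = _RAMPS[scale.name]
    t = scale.interp_param(float(value))
    n_seg = len(stops) - 1
    pos = t * n_seg
    i = min(int(pos), n_seg - 1)
    u = pos - i
    a, b = stops[i], stops[i + 1]
    rgb = tuple(round(a[k] + (b[k] - a[k]) * u) for k in range(3))
    return _hex(rgb)  # type: ignore[arg-type]


def map_category(code: int, palette: CategoryPalette) -> str:
    return palette.color(int(code))


def map_binary(value: int, palette: BinaryPalette) -> str | None:
    """-1 -> loss color, +1 -> gain color, 0 -> None (no glyph drawn)."""
    v = int(value)
    if v == -1:
        return palette.color_loss
    if v == 1:
        return palette.color_gain
    if v == 0:
        return None
    raise ValueError(f"binary value must be -1, 0 or +1, got {value}")


def category_palette_for(labels: list[str], outline: bool = False) -> CategoryPalette:
    """A palette with one default-cycle color per label, order-stable."""
    cols = tuple(
        DEFAULT_CATEGORY_COLORS[i % len(DEFAULT_CATEGORY_COLORS)]
        for i in range(len(labels))
    )
    return CategoryPalette(colors=cols, outline_mode=outline, labels=tuple(labels))
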