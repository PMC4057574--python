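"""The wallpaper grid and polygonal-line renderings of sequence vectors.

The grid is generated from a cruciform motif: a central E with C to the
right, A above, T below and G to the left, tiled by a knight's-move
translation.  Algebraically every cell is determined by the modular rule
cell(x, y) = (origin + x + 2y) mod 5, so each horizontal row cycles through
E-C-A-T-G and the letter above an E is always A.

A sequence vector is charted as one point per explicit entry at
(place number, base index) with E = 0, joined into a polyline; an SVG
rendering with the five index levels labeled is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .core_group import DNA, BaseSymbol
from .sequence_model import SeqVector

__all__ = ["WallpaperGrid", "build_grid", "orbit_path", "render_text", "orbit_svg"]


@dataclass(frozen=True)
class WallpaperGrid:
    """A width x height window of the infinite five-letter wallpaper pattern."""

    width: int
    height: int
    origin: BaseSymbol = BaseSymbol(0, DNA)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")

    def cell(self, x: int, y: int) -> BaseSymbol:
        """The letter at (x right, y up); negative coordinates permitted."""
        return BaseSymbol((self.origin.index + x + 2 * y) % 5, self.origin.alphabet)

    def rows(self) -> List[str]:
        """Rows of letters, top row = highest y."""
        return [
            "".join(self.cell(x, y).letter for x in range(self.width))
            for y in range(self.height - 1, -1, -1)
        ]


def build_grid(
    width: int, height: int, origin: Optional[BaseSymbol] = None
) -> WallpaperGrid:
    """Construct the grid window; default origin is E at (0, 0)."""
    return WallpaperGrid(width, height, origin or BaseSymbol(0, DNA))


def render_text(grid: WallpaperGrid) -> str:
    """Fixed-width character rendering, deterministic across runs."""
    return "\n".join(grid.rows())


def orbit_path(
    s: SeqVector, include_implicit: bool = False
) -> List[Tuple[int, int]]:
    """Chart a sequence as (place, base index) points for a polyline.

    One point per explicit entry; with ``include_implicit`` every place in
    1..max_place is plotted, implicit E's at index 0.
    """
    if include_implicit:
        return [(p, s.index_at(p)) for p in range(1, s.max_place + 1)]
    return [(p, i) for p, i in sorted(s.entries.items())]


_SVG_W = 60  # px per place
_SVG_H = 40  # px per index level


def orbit_svg(
    s: SeqVector, include_implicit: bool = False, title: str = ""
) -> str:
    """A self-contained SVG polyline of the orbit with labeled index levels."""
    points = orbit_path(s, include_implicit)
    max_place = max((p for p, _ in points), default=1)
    width = (max_place + 1) * _SVG_W + 40
    height = 6 * _SVG_H

    def xy(place: int, idx: int) -> Tuple[int, int]:
        return 40 + place * _SVG_W, height - _SVG_H * (idx + 1)

    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="monospace" font-size="12">',
    ]
    if title:
        lines.append(f'<text x="10" y="14">{title}</text>')
    for idx in range(5):
        letter = BaseSymbol(idx, s.alphabet).letter
        _, y = xy(0, idx)
        lines.append(
            f'<line x1="40" y1="{y}" x2="{width - 10}" y2="{y}" '
            f'stroke="#ccc" stroke-width="1"/>'
        )
        lines.append(f'<text x="10" y="{y + 4}">{letter}={idx}</text>')
    if points:
        path = " ".join("{},{}".format(*xy(p, i)) for p, i in points)
        lines.append(
            f'<polyline points="{path}" fill="none" stroke="#1f4e9c" '
            f'stroke-width="2"/>'
        )
        for p, i in points:
            x, y = xy(p, i)
            lines.append(f'<circle cx="{x}" cy="{y}" r="3" fill="#1f4e9c"/>')
            lines.append(f'<text x="{x - 4}" y="{height - 6}">{p}</text>')
    lines.append("</svg>")
    return "\n".join(lines)
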