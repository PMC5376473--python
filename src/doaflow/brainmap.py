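"""2D head-map rendering of a dominant information flow.

Draws the seven 10-20 electrode positions inside a unit head circle,
shades the source group blue and the target group red, and draws one
arrow from the source centroid to the target centroid whose stroke
width is proportional to the TE value (omitted when the value is 0).
SVG output is written directly as text so identical inputs produce
byte-identical files; PNG goes through matplotlib.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .bipartition import Bipartition

__all__ = ["HEAD_LAYOUT_7CH", "render_flow"]

# 2D projection of the 10-20 positions used clinically (unit head
# circle, nose up: x right, y anterior). Left/right homologues mirror
# in x; Cz sits at the vertex.
HEAD_LAYOUT_7CH: dict[str, tuple[float, float]] = {
    "Fp1": (-0.26, 0.82),
    "Fp2": (0.26, 0.82),
    "F3": (-0.34, 0.44),
    "F4": (0.34, 0.44),
    "P3": (-0.34, -0.44),
    "P4": (0.34, -0.44),
    "Cz": (0.0, 0.0),
}

_SOURCE_COLOR = "#2b6cb0"  # blue
_TARGET_COLOR = "#c53030"  # red


def _centroid(names, layout) -> tuple[float, float]:
    pts = np.array([layout[n] for n in names])
    return float(pts[:, 0].mean()), float(pts[:, 1].mean())


def _svg_coord(xy: tuple[float, float], size: float) -> tuple[float, float]:
    # unit circle -> pixel canvas, y flipped (SVG y grows downward)
    half = size / 2
    return half + xy[0] * half * 0.85, half - xy[1] * half * 0.85


def render_flow(
    bipartition: Bipartition,
    value: float,
    layout: Mapping[str, tuple[float, float]] | None = None,
    out: str | Path = "flow.svg",
    width_per_nat: float = 120.0,
    size: float = 360.0,
) -> Path:
    """Render one bipartition's flow to SVG or PNG (by file suffix)."""
    layout = dict(HEAD_LAYOUT_7CH if layout is None else layout)
    unknown = [c for c in (*bipartition.source, *bipartition.target) if c not in layout]
    if unknown:
        raise KeyError(f"channels missing from layout: {unknown}")
    if value < 0:
        raise ValueError("flow value must be non-negative")
    out = Path(out)
    if out.suffix.lower() == ".png":
        _render_png(bipartition, value, layout, out, width_per_nat)
        return out
    out.write_text(_svg_text(bipartition, value, layout, width_per_nat, size))
    return out


def _svg_text(bp: Bipartition, value: float, layout, width_per_nat, size) -> str:
    half = size / 2
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size:.0f}" height="{size:.0f}" '
        f'viewBox="0 0 {size:.0f} {size:.0f}">',
        f'<circle cx="{half:.1f}" cy="{half:.1f}" r="{half * 0.92:.1f}" '
        'fill="none" stroke="#444" stroke-width="2"/>',
        # nose tick
        f'<path d="M {half - 10:.1f} {half - half * 0.92 + 2:.1f} '
        f'L {half:.1f} {half - half * 0.98:.1f} '
        f'L {half + 10:.1f} {half - half * 0.92 + 2:.1f}" '
        'fill="none" stroke="#444" stroke-width="2"/>',
    ]
    for name, xy in sorted(layout.items()):
        cx, cy = _svg_coord(xy, size)
        if name in bp.source:
            fill, opacity = _SOURCE_COLOR, "0.55"
        elif name in bp.target:
            fill, opacity = _TARGET_COLOR, "0.55"
        else:
            fill, opacity = "#999999", "0.35"
        parts.append(
            f'<circle cx="{cx:.2f}" cy="{cy:.2f}" r="16" fill="{fill}" '
            f'fill-opacity="{opacity}"/>'
        )
        parts.append(
            f'<text x="{cx:.2f}" y="{cy + 4:.2f}" text-anchor="middle" '
            f'font-size="11" font-family="sans-serif">{name}</text>'
        )
    stroke = value * width_per_nat
    if stroke > 0:
        (x0, y0) = _svg_coord(_centroid(bp.source, layout), size)
        (x1, y1) = _svg_coord(_centroid(bp.target, layout), size)
        dx, dy = x1 - x0, y1 - y0
        norm = max((dx * dx + dy * dy) ** 0.5, 1e-9)
        # arrowhead: two short strokes at the target end
        hx, hy = dx / norm, dy / norm
        px, py = -hy, hx
        ah = max(stroke * 1.6, 8.0)
        parts.append(
            f'<line x1="{x0:.2f}" y1="{y0:.2f}" x2="{x1:.2f}" y2="{y1:.2f}" '
            f'stroke="#222" stroke-width="{stroke:.4f}" stroke-linecap="round"/>'
        )
        for s in (+1, -1):
            bx = x1 - hx * ah + s * px * ah * 0.6
            by = y1 - hy * ah + s * py * ah * 0.6
            parts.append(
                f'<line x1="{bx:.2f}" y1="{by:.2f}" x2="{x1:.2f}" y2="{y1:.2f}" '
                f'stroke="#222" stroke-width="{stroke:.4f}" stroke-linecap="round"/>'
            )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _render_png(bp: Bipartition, value: float, layout, out: Path, width_per_nat) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="#444", lw=2))
    for name, (x, y) in layout.items():
        color = (
            _SOURCE_COLOR if name in bp.source
            else _TARGET_COLOR if name in bp.target
            else "#999999"
        )
        ax.add_patch(plt.Circle((x, y), 0.09, color=color, alpha=0.55))
        ax.text(x, y, name, ha="center", va="center", fontsize=8)
    if value > 0:
        x0, y0 = _centroid(bp.source, layout)
        x1, y1 = _centroid(bp.target, layout)
        ax.annotate(
            "",
            xy=(x1, y1),
            xytext=(x0, y0),
            arrowprops=dict(arrowstyle="-|>", lw=value * width_per_nat / 40, color="#222"),
        )
    ax.set_xlim(-1.2, 1.2)
    ax.set_ylim(-1.2, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
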