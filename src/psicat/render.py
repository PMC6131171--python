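"""Deterministic rendering of targets and primers to SVG and PNG.

Stimuli live in degrees of visual angle (centre origin, y-up); rasters use
``pixels_per_degree`` with the image origin top-left and y-down.  Targets
are drawn white-on-black, primers as red line angles on black.  With
antialiasing off (the default) renders are bit-reproducible and pixel
counts track vector ink areas, which the matched-feature tests rely on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from .geometry import GeometryConfig, PrimerStimulus, TargetStimulus, mouth_edge_directions

__all__ = ["Rendered", "render", "render_png", "render_svg"]

_SS = 4  # supersampling factor when antialiasing


@dataclass(frozen=True)
class Rendered:
    svg: str
    image: Image.Image

    @property
    def png_bytes(self) -> bytes:
        buf = io.BytesIO()
        self.image.save(buf, format="PNG")
        return buf.getvalue()


def _to_px(xy, config: GeometryConfig, ppd: float):
    x, y = xy
    half = config.canvas_size / 2.0
    return ((x + half) * ppd, (half - y) * ppd)


def render_png(
    stimulus,
    config: GeometryConfig,
    pixels_per_degree: float = 32.0,
    antialias: bool = False,
) -> Image.Image:
    if pixels_per_degree <= 0:
        raise ValueError("pixels_per_degree must be positive")
    ppd = pixels_per_degree * (_SS if antialias else 1)
    size = int(round(config.canvas_size * ppd))
    img = Image.new("RGB", (size, size), config.background_color)
    draw = ImageDraw.Draw(img)
    if isinstance(stimulus, TargetStimulus):
        for ind in stimulus.inducers:
            cx, cy = _to_px(ind.center, config, ppd)
            r = ind.radius * ppd
            bbox = [cx - r, cy - r, cx + r, cy + r]
            # kept disc sector spans (360 - mouth) degrees; PIL angles run
            # clockwise on screen, i.e. the negative of the y-up convention
            start = ind.mouth_angle / 2.0 - ind.mouth_orientation
            draw.pieslice(bbox, start, start + 360.0 - ind.mouth_angle, fill=config.target_color)
    elif isinstance(stimulus, PrimerStimulus):
        w = max(1, int(round(config.primer_line_width * ppd)))
        for seg in stimulus.segments:
            draw.line(
                [_to_px(seg.start, config, ppd), _to_px(seg.end, config, ppd)],
                fill=config.primer_color,
                width=w,
            )
    else:
        raise TypeError(f"cannot render {type(stimulus).__name__}")
    if antialias:
        out = int(round(config.canvas_size * pixels_per_degree))
        img = img.resize((out, out), Image.LANCZOS)
    return img


def _svg_pieslice(cx, cy, r, mouth_orientation, mouth_angle, color):
    # arc endpoints at the mouth edges, sweeping the kept (360 - mouth) sector
    a0 = np.radians(mouth_orientation + mouth_angle / 2.0)
    a1 = np.radians(mouth_orientation - mouth_angle / 2.0)
    # screen y-down: negate the y component of direction vectors
    x0, y0 = cx + r * np.cos(a0), cy - r * np.sin(a0)
    x1, y1 = cx + r * np.cos(a1), cy - r * np.sin(a1)
    large = 1 if (360.0 - mouth_angle) > 180.0 else 0
    return (
        f'<path d="M {cx:.4f} {cy:.4f} L {x0:.4f} {y0:.4f} '
        f'A {r:.4f} {r:.4f} 0 {large} 1 {x1:.4f} {y1:.4f} Z" fill="{color}"/>'
    )


def render_svg(stimulus, config: GeometryConfig, pixels_per_degree: float = 32.0) -> str:
    if pixels_per_degree <= 0:
        raise ValueError("pixels_per_degree must be positive")
    ppd = pixels_per_degree
    size = config.canvas_size * ppd
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size:.0f}" '
        f'height="{size:.0f}" viewBox="0 0 {size:.4f} {size:.4f}">',
        f'<rect width="{size:.4f}" height="{size:.4f}" fill="{config.background_color}"/>',
    ]
    if isinstance(stimulus, TargetStimulus):
        for ind in stimulus.inducers:
            cx, cy = _to_px(ind.center, config, ppd)
            parts.append(
                _svg_pieslice(
                    cx, cy, ind.radius * ppd, ind.mouth_orientation, ind.mouth_angle,
                    config.target_color,
                )
            )
    elif isinstance(stimulus, PrimerStimulus):
        w = config.primer_line_width * ppd
        for seg in stimulus.segments:
            (x0, y0), (x1, y1) = _to_px(seg.start, config, ppd), _to_px(seg.end, config, ppd)
            parts.append(
                f'<line x1="{x0:.4f}" y1="{y0:.4f}" x2="{x1:.4f}" y2="{y1:.4f}" '
                f'stroke="{config.primer_color}" stroke-width="{w:.4f}" stroke-linecap="round"/>'
            )
    else:
        raise TypeError(f"cannot render {type(stimulus).__name__}")
    parts.append("</svg>")
    return "\n".join(parts)


def render(stimulus, config: GeometryConfig, pixels_per_degree: float = 32.0,
           antialias: bool = False) -> Rendered:
    """Render a stimulus to both vector (SVG) and raster (PNG) forms."""
    return Rendered(
        svg=render_svg(stimulus, config, pixels_per_degree),
        image=render_png(stimulus, config, pixels_per_degree, antialias),
    )
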