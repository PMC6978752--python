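"""Gene-diagram rendering of predicted sites.

Draws a horizontal transcript axis with the UTR/CDS boundaries marked and
one vertical tick per binding site at its scaled position — conserved sites
red, non-conserved black (in text mode ``|`` vs ``:``). Output is a plain
SVG document or a monospace text diagram; both are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
from xml.sax.saxutils import escape

from .seed_scan import Site


@dataclass
class SiteMap:
    transcript_id: str
    length: int
    cds_start: int
    cds_end: int
    sites: Sequence[Site] = field(default_factory=list)
    width: int = 600
    conserved_color: str = "red"
    nonconserved_color: str = "black"

    def __post_init__(self) -> None:
        if not 0 <= self.cds_start < self.cds_end <= self.length:
            raise ValueError("CDS boundaries outside the transcript")
        for site in self.sites:
            if not 0 <= site.start < site.end <= self.length:
                raise ValueError(
                    f"site [{site.start}, {site.end}) outside transcript "
                    f"of length {self.length}"
                )


def render_site_map(site_map: SiteMap, format: str = "svg") -> str:
    if format == "svg":
        return _render_svg(site_map)
    if format == "text":
        return _render_text(site_map)
    raise ValueError(f"unsupported site-map format {format!r} (svg or text)")


def _x(position: int, site_map: SiteMap, margin: int) -> float:
    usable = site_map.width - 2 * margin
    return margin + usable * position / site_map.length


def _render_svg(m: SiteMap) -> str:
    margin, axis_y, tick_h, height = 30, 60, 24, 100
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{m.width}" '
        f'height="{height}" viewBox="0 0 {m.width} {height}">',
        f'<title>{escape(m.transcript_id)}</title>',
        f'<text x="{margin}" y="20" font-family="monospace" font-size="12">'
        f"{escape(m.transcript_id)} ({m.length} nt)</text>",
        f'<line x1="{_x(0, m, margin):.1f}" y1="{axis_y}" '
        f'x2="{_x(m.length, m, margin):.1f}" y2="{axis_y}" '
        'stroke="black" stroke-width="1"/>',
    ]
    # CDS drawn as a thicker bar between the region boundaries
    parts.append(
        f'<rect x="{_x(m.cds_start, m, margin):.1f}" y="{axis_y - 4}" '
        f'width="{_x(m.cds_end, m, margin) - _x(m.cds_start, m, margin):.1f}" '
        'height="8" fill="lightgray" stroke="black" stroke-width="0.5"/>'
    )
    for boundary, label in ((m.cds_start, "CDS start"), (m.cds_end, "CDS end")):
        x = _x(boundary, m, margin)
        parts.append(
            f'<line x1="{x:.1f}" y1="{axis_y - 8}" x2="{x:.1f}" '
            f'y2="{axis_y + 8}" stroke="black" stroke-width="0.5" '
            f'stroke-dasharray="2,2"><title>{label} ({boundary})</title></line>'
        )
    for site in m.sites:
        x = _x((site.start + site.end) // 2, m, margin)
        color = m.conserved_color if site.conserved else m.nonconserved_color
        parts.append(
            f'<line x1="{x:.1f}" y1="{axis_y - tick_h / 2:.1f}" x2="{x:.1f}" '
            f'y2="{axis_y + tick_h / 2:.1f}" stroke="{color}" stroke-width="2">'
            f"<title>[{site.start}, {site.end}) {site.region} "
            f"match_len={site.match_len}</title></line>"
        )
    parts.append(
        f'<text x="{margin}" y="{height - 8}" font-family="monospace" '
        'font-size="10">tick: binding site (red = conserved); '
        "gray bar: CDS</text>"
    )
    parts.append("</svg>")
    return "\n".join(parts)


def _render_text(m: SiteMap, columns: int = 80) -> str:
    def col(position: int) -> int:
        return min(columns - 1, position * columns // m.length)

    axis = ["-"] * columns
    axis[col(m.cds_start)] = "["
    axis[col(m.cds_end - 1)] = "]"
    ticks = [" "] * columns
    for site in m.sites:
        c = col((site.start + site.end) // 2)
        ticks[c] = "|" if site.conserved else ":"
    return "\n".join(
        [
            f"{m.transcript_id} ({m.length} nt)",
            "".join(ticks),
            "".join(axis),
            "legend: | conserved site, : non-conserved site, [ ] CDS bounds",
        ]
    )
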