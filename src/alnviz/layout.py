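"""Layout engines for the four diagram types.

Each layout maps normalised alignments (or coverage tracks) onto a fixed
1000-unit-wide logical canvas and returns backend-neutral
:class:`~alnviz.draw.DrawCommand` lists; :func:`alnviz.draw.render` turns
them into SVG or TikZ.  Multi-target / multi-query diagrams return one
command list per group, which the CLI writes as one file per group.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from typing import Sequence

from .chimera import ChimeraCall
from .coverage import CoverageTrack, GenomeCoverage
from .draw import DrawCommand
from .model import AlignmentRecord, AlignmentSet, Strand, group_by

__all__ = [
    "CANVAS_WIDTH",
    "layout_alignment_diagram",
    "layout_contig_alignment_diagram",
    "layout_coverage_map",
    "layout_genome_coverage",
    "target_palette",
    "heat_color",
]

CANVAS_WIDTH = 1000.0
MARGIN = 30.0
ROW_HEIGHT = 10.0
ROW_PITCH = 18.0

# 12-colour palette assigned to targets by order of first appearance,
# wrapping afterwards
PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
)
TARGET_BAR_COLOR = "#cc0000"


def target_palette(alignments: AlignmentSet) -> "OrderedDict[str, str]":
    """Stable target -> colour map by order of first appearance."""
    colors: OrderedDict[str, str] = OrderedDict()
    for name in alignments.target_names():
        colors[name] = PALETTE[len(colors) % len(PALETTE)]
    return colors


def _lighten(hex_color: str, amount: float = 0.65) -> str:
    """Blend a colour toward white by ``amount``."""
    c = hex_color.lstrip("#")
    r, g, b = (int(c[i : i + 2], 16) for i in (0, 2, 4))
    mix = lambda v: round(v + (255 - v) * amount)
    return f"#{mix(r):02x}{mix(g):02x}{mix(b):02x}"


def heat_color(t: float) -> str:
    """White -> red heat scale for a normalised count in [0, 1]."""
    t = min(max(t, 0.0), 1.0)
    v = round(255 * (1.0 - t))
    return f"#ff{v:02x}{v:02x}"


def _clip_line(x1: float, x2: float, y: float, lo: float, hi: float,
               commands: list[DrawCommand]) -> tuple[float, float]:
    """Clip a horizontal line to [lo, hi], marking clipped ends with arrows."""
    arrow = 5.0
    if x1 < lo:
        commands.append(DrawCommand(
            kind="polygon", fill="#000000", role="clip-arrow",
            points=((lo, y), (lo + arrow, y - arrow / 2), (lo + arrow, y + arrow / 2)),
        ))
        x1 = lo + arrow
    if x2 > hi:
        commands.append(DrawCommand(
            kind="polygon", fill="#000000", role="clip-arrow",
            points=((hi, y), (hi - arrow, y - arrow / 2), (hi - arrow, y + arrow / 2)),
        ))
        x2 = hi - arrow
    return x1, x2


def layout_alignment_diagram(
    alignments: AlignmentSet,
) -> "OrderedDict[str, list[DrawCommand]]":
    """Alignments grouped by target, one section per target.

    Each target is a red bar scaled to its length; each alignment is a
    rectangle at its target interval, rows ordered by query name and, for
    queries with several alignments, by start position on the target.  A
    line through each rectangle shows the full query at the same scale,
    placed so the aligned query interval coincides with the rectangle;
    ends running off the canvas are clipped with arrow heads.
    """
    drawable = CANVAS_WIDTH - 2 * MARGIN
    sections: OrderedDict[str, list[DrawCommand]] = OrderedDict()
    for target, group in group_by(alignments, "target").items():
        length = group[0].target_length or max(r.target_end for r in group)
        scale = drawable / length
        cmds: list[DrawCommand] = [
            DrawCommand(kind="text", x=MARGIN, y=16.0, text=target,
                        font_size=12.0, role="title"),
            DrawCommand(kind="rectangle", x=MARGIN, y=24.0,
                        width=length * scale, height=8.0,
                        fill=TARGET_BAR_COLOR, role="target-bar"),
        ]
        rows = sorted(group, key=lambda r: (r.query_name, r.target_start))
        for i, rec in enumerate(rows):
            y = 44.0 + i * ROW_PITCH
            rx = MARGIN + rec.target_start * scale
            rw = rec.target_span * scale
            cmds.append(DrawCommand(
                kind="rectangle", x=rx, y=y, width=rw, height=ROW_HEIGHT,
                fill="#1f77b4", stroke="#000000", role="alignment",
            ))
            # query extent line through the rectangle's vertical centre;
            # forward: bases before query_start extend left of the rectangle
            ly = y + ROW_HEIGHT / 2
            if rec.strand is Strand.FORWARD:
                lx1 = rx - rec.query_start * scale
                lx2 = rx + rw + (rec.query_length - rec.query_end) * scale
            else:
                lx1 = rx - (rec.query_length - rec.query_end) * scale
                lx2 = rx + rw + rec.query_start * scale
            lx1, lx2 = _clip_line(lx1, lx2, ly, 2.0, CANVAS_WIDTH - 2.0, cmds)
            cmds.append(DrawCommand(
                kind="line", x=lx1, y=ly, x2=lx2, y2=ly,
                stroke="#000000", role="query-line",
            ))
        sections[target] = cmds
    return sections


MAX_ALIGNMENTS_PER_QUERY = 10


def layout_contig_alignment_diagram(
    alignments: AlignmentSet,
    chimera_calls: Sequence[ChimeraCall] = (),
    chimeras_only: bool = False,
) -> "OrderedDict[str, list[DrawCommand]]":
    """Alignments grouped by query, one section per query.

    Each query is an outline box scaled to its length; the ten longest
    alignments (by query span, ties by input order) are drawn inside at
    their query intervals, coloured by target and shaded light-to-dark
    along the target (direction reversed for reverse strand).  Chimeric
    queries get a 'C' mark; with ``chimeras_only`` only chimeric queries
    are drawn and the mark is suppressed.
    """
    drawable = CANVAS_WIDTH - 2 * MARGIN
    colors = target_palette(alignments)
    chimeric = {c.query_name for c in chimera_calls}
    box_h = 28.0
    sections: OrderedDict[str, list[DrawCommand]] = OrderedDict()
    for query, group in group_by(alignments, "query").items():
        if chimeras_only and query not in chimeric:
            continue
        qlen = group[0].query_length
        scale = drawable / qlen
        cmds: list[DrawCommand] = [
            DrawCommand(kind="text", x=MARGIN, y=16.0, text=query,
                        font_size=12.0, role="title"),
            DrawCommand(kind="rectangle", x=MARGIN, y=24.0,
                        width=qlen * scale, height=box_h,
                        fill=None, stroke="#000000", role="query-box"),
        ]
        order = sorted(range(len(group)), key=lambda i: (-group[i].query_span, i))
        shown = sorted(order[:MAX_ALIGNMENTS_PER_QUERY])
        used_targets: OrderedDict[str, str] = OrderedDict()
        for i in shown:
            rec = group[i]
            base = colors[rec.target_name]
            used_targets.setdefault(rec.target_name, base)
            light = _lighten(base)
            grad = (light, base) if rec.strand is Strand.FORWARD else (base, light)
            cmds.append(DrawCommand(
                kind="rectangle",
                x=MARGIN + rec.query_start * scale, y=24.0 + 3.0,
                width=rec.query_span * scale, height=box_h - 6.0,
                gradient=grad, role="alignment",
            ))
        if query in chimeric and not chimeras_only:
            cmds.append(DrawCommand(
                kind="text", x=MARGIN + qlen * scale + 8.0, y=24.0 + box_h / 2 + 5.0,
                text="C", font_size=14.0, role="chimera-mark",
            ))
        y = 24.0 + box_h + 20.0
        for name, col in used_targets.items():
            cmds.append(DrawCommand(kind="rectangle", x=MARGIN, y=y - 8.0,
                                    width=10.0, height=8.0, fill=col,
                                    role="legend-swatch"))
            cmds.append(DrawCommand(kind="text", x=MARGIN + 14.0, y=y,
                                    text=name, font_size=9.0, role="legend-label"))
            y += 14.0
        sections[query] = cmds
    return sections


def layout_coverage_map(track: CoverageTrack, shape: str = "square") -> list[DrawCommand]:
    """Heat map of one coverage track: wrapped square or single long bar.

    One filled cell per bin; colour is the white-to-red heat scale
    normalised to the track's maximum count (an all-zero track renders in
    the zero colour).
    """
    if shape not in ("square", "long"):
        raise ValueError(f"shape must be 'square' or 'long', got {shape!r}")
    n = track.n_bins
    if n == 0:
        raise ValueError(f"{track.target_name}: empty coverage track")
    drawable = CANVAS_WIDTH - 2 * MARGIN
    vmax = track.max_count
    cmds: list[DrawCommand] = [
        DrawCommand(kind="text", x=MARGIN, y=16.0, text=track.target_name,
                    font_size=12.0, role="title"),
    ]
    top = 24.0
    if shape == "square":
        side = math.ceil(math.sqrt(n))
        cell = drawable / side
        for i, count in enumerate(track.counts):
            row, col = divmod(i, side)
            cmds.append(DrawCommand(
                kind="rectangle", x=MARGIN + col * cell, y=top + row * cell,
                width=cell, height=cell,
                fill=heat_color(0.0 if vmax == 0 else int(count) / vmax),
                role="cell",
            ))
    else:
        cell = drawable / n
        for i, count in enumerate(track.counts):
            cmds.append(DrawCommand(
                kind="rectangle", x=MARGIN + i * cell, y=top,
                width=cell, height=24.0,
                fill=heat_color(0.0 if vmax == 0 else int(count) / vmax),
                role="cell",
            ))
    return cmds


def layout_genome_coverage(coverage: GenomeCoverage) -> list[DrawCommand]:
    """All targets' heat maps stacked in order at one constant cell size.

    Every bin spans the same number of bases (shared bin size), and every
    cell has the same width, so row length is proportional to target
    length.  The colour scale is normalised jointly over all targets.
    """
    if not coverage.tracks:
        return []
    label_w = 130.0
    drawable = CANVAS_WIDTH - MARGIN - label_w
    max_bins = max(t.n_bins for t in coverage.tracks)
    cell_w = drawable / max_bins
    cell_h = 16.0
    pitch = cell_h + 8.0
    vmax = coverage.max_count
    cmds: list[DrawCommand] = []
    for row, track in enumerate(coverage.tracks):
        y = 16.0 + row * pitch
        cmds.append(DrawCommand(
            kind="text", x=MARGIN, y=y + cell_h - 4.0, text=track.target_name,
            font_size=10.0, role="label",
        ))
        for i, count in enumerate(track.counts):
            cmds.append(DrawCommand(
                kind="rectangle", x=label_w + i * cell_w, y=y,
                width=cell_w, height=cell_h,
                fill=heat_color(0.0 if vmax == 0 else int(count) / vmax),
                role="cell",
            ))
    return cmds
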