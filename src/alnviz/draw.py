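"""Backend-neutral drawing primitives and the SVG / TikZ drawers.

Diagram layouts emit a flat list of :class:`DrawCommand` in paint order
(later commands draw on top).  A drawer turns that stream into a
standalone document; both drawers here are byte-deterministic for a fixed
command list, so repeated runs of the pipeline produce identical files.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import IO, Sequence

__all__ = ["DrawCommand", "render", "render_svg", "render_tex", "BACKENDS"]

BACKENDS = ("svg", "tex")


@dataclass(frozen=True)
class DrawCommand:
    """One drawing primitive in abstract canvas units (y grows downward).

    kind:
        ``line``       -- (x, y) to (x2, y2), stroked
        ``rectangle``  -- (x, y, width, height), filled and/or stroked
        ``text``       -- baseline-left at (x, y)
        ``polygon``    -- closed ``points``, filled

    ``gradient`` is a (left colour, right colour) pair painting a
    horizontal linear gradient across a rectangle; it overrides ``fill``.
    ``role`` is a semantic tag ("target-bar", "alignment", "cell", ...)
    used for styling and for structural checks; it does not affect
    geometry.
    """

    kind: str
    x: float = 0.0
    y: float = 0.0
    x2: float = 0.0
    y2: float = 0.0
    width: float = 0.0
    height: float = 0.0
    text: str = ""
    font_size: float = 10.0
    points: tuple[tuple[float, float], ...] = ()
    fill: str | None = None
    stroke: str | None = None
    gradient: tuple[str, str] | None = None
    role: str = ""

    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) extent of the command."""
        if self.kind == "line":
            return (min(self.x, self.x2), min(self.y, self.y2),
                    max(self.x, self.x2), max(self.y, self.y2))
        if self.kind == "rectangle":
            return (self.x, self.y, self.x + self.width, self.y + self.height)
        if self.kind == "text":
            # approximate text box: 0.6 em per character, one em tall
            w = 0.6 * self.font_size * len(self.text)
            return (self.x, self.y - self.font_size, self.x + w, self.y)
        if self.kind == "polygon":
            xs = [p[0] for p in self.points]
            ys = [p[1] for p in self.points]
            return (min(xs), min(ys), max(xs), max(ys))
        raise ValueError(f"unknown command kind {self.kind!r}")


def canvas_size(commands: Sequence[DrawCommand], pad: float = 10.0) -> tuple[float, float]:
    """Tight canvas covering every command, padded."""
    if not commands:
        return (pad * 2, pad * 2)
    max_x = max(c.bounds()[2] for c in commands)
    max_y = max(c.bounds()[3] for c in commands)
    return (max_x + pad, max_y + pad)


def _fmt(v: float) -> str:
    # two-decimal fixed formatting keeps output byte-deterministic
    s = f"{v:.2f}"
    return s.rstrip("0").rstrip(".") if "." in s else s


def _xml_escape(s: str) -> str:
    return (
        s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def render_svg(commands: Sequence[DrawCommand]) -> str:
    """Render commands to a standalone SVG document string."""
    width, height = canvas_size(commands)
    out = io.StringIO()
    out.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    out.write(
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
    )
    gradients: dict[tuple[str, str], str] = {}
    for cmd in commands:
        if cmd.gradient is not None and cmd.gradient not in gradients:
            gradients[cmd.gradient] = f"grad{len(gradients)}"
    if gradients:
        out.write("<defs>\n")
        for (c1, c2), gid in gradients.items():
            out.write(
                f'<linearGradient id="{gid}" x1="0" y1="0" x2="1" y2="0">'
                f'<stop offset="0" stop-color="{c1}"/>'
                f'<stop offset="1" stop-color="{c2}"/>'
                f"</linearGradient>\n"
            )
        out.write("</defs>\n")
    for cmd in commands:
        role = f' class="{_xml_escape(cmd.role)}"' if cmd.role else ""
        if cmd.kind == "line":
            stroke = cmd.stroke or "#000000"
            out.write(
                f'<line{role} x1="{_fmt(cmd.x)}" y1="{_fmt(cmd.y)}" '
                f'x2="{_fmt(cmd.x2)}" y2="{_fmt(cmd.y2)}" stroke="{stroke}"/>\n'
            )
        elif cmd.kind == "rectangle":
            if cmd.gradient is not None:
                fill = f"url(#{gradients[cmd.gradient]})"
            else:
                fill = cmd.fill or "none"
            stroke = f' stroke="{cmd.stroke}"' if cmd.stroke else ""
            out.write(
                f'<rect{role} x="{_fmt(cmd.x)}" y="{_fmt(cmd.y)}" '
                f'width="{_fmt(cmd.width)}" height="{_fmt(cmd.height)}" '
                f'fill="{fill}"{stroke}/>\n'
            )
        elif cmd.kind == "text":
            fill = cmd.fill or "#000000"
            out.write(
                f'<text{role} x="{_fmt(cmd.x)}" y="{_fmt(cmd.y)}" '
                f'font-family="Helvetica,sans-serif" font-size="{_fmt(cmd.font_size)}" '
                f'fill="{fill}">{_xml_escape(cmd.text)}</text>\n'
            )
        elif cmd.kind == "polygon":
            pts = " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in cmd.points)
            fill = cmd.fill or "#000000"
            out.write(f'<polygon{role} points="{pts}" fill="{fill}"/>\n')
        else:
            raise ValueError(f"unknown command kind {cmd.kind!r}")
    out.write("</svg>\n")
    return out.getvalue()


def _tex_escape(s: str) -> str:
    specials = "\\{}_^#&$%~"
    out = []
    for ch in s:
        if ch == "\\":
            out.append(r"\textbackslash{}")
        elif ch in specials:
            out.append("\\" + ch)
        else:
            out.append(ch)
    return "".join(out)


def render_tex(commands: Sequence[DrawCommand]) -> str:
    """Render commands to a standalone TikZ document string.

    Canvas units map to points; the y axis is flipped so layouts can keep
    the screen convention (y grows downward).
    """
    _, height = canvas_size(commands)

    colors: dict[str, str] = {}

    def color(c: str) -> str:
        c = c.lstrip("#")
        if c not in colors:
            colors[c] = f"col{len(colors)}"
        return colors[c]

    body = io.StringIO()
    for cmd in commands:
        y = height - cmd.y
        if cmd.kind == "line":
            y2 = height - cmd.y2
            body.write(
                f"\\draw[{color(cmd.stroke or '#000000')}] "
                f"({_fmt(cmd.x)}pt,{_fmt(y)}pt) -- ({_fmt(cmd.x2)}pt,{_fmt(y2)}pt);\n"
            )
        elif cmd.kind == "rectangle":
            y_bot = height - (cmd.y + cmd.height)
            corners = (
                f"({_fmt(cmd.x)}pt,{_fmt(y_bot)}pt) rectangle "
                f"({_fmt(cmd.x + cmd.width)}pt,{_fmt(y)}pt)"
            )
            opts = []
            if cmd.gradient is not None:
                opts.append(
                    f"left color={color(cmd.gradient[0])},right color={color(cmd.gradient[1])}"
                )
            elif cmd.fill:
                opts.append(f"fill={color(cmd.fill)}")
            if cmd.stroke:
                opts.append(f"draw={color(cmd.stroke)}")
            body.write(f"\\path[{','.join(opts) or 'draw'}] {corners};\n")
        elif cmd.kind == "text":
            body.write(
                f"\\node[anchor=base west,font=\\fontsize{{{_fmt(cmd.font_size)}}}"
                f"{{{_fmt(cmd.font_size * 1.2)}}}\\selectfont,"
                f"{color(cmd.fill or '#000000')}] "
                f"at ({_fmt(cmd.x)}pt,{_fmt(y)}pt) {{{_tex_escape(cmd.text)}}};\n"
            )
        elif cmd.kind == "polygon":
            pts = " -- ".join(f"({_fmt(px)}pt,{_fmt(height - py)}pt)" for px, py in cmd.points)
            body.write(f"\\path[fill={color(cmd.fill or '#000000')}] {pts} -- cycle;\n")
        else:
            raise ValueError(f"unknown command kind {cmd.kind!r}")

    out = io.StringIO()
    out.write("\\documentclass[tikz]{standalone}\n")
    out.write("\\usepackage{tikz}\n")
    for hexval, name in colors.items():
        out.write(f"\\definecolor{{{name}}}{{HTML}}{{{hexval.upper()}}}\n")
    out.write("\\begin{document}\n\\begin{tikzpicture}\n")
    out.write(body.getvalue())
    out.write("\\end{tikzpicture}\n\\end{document}\n")
    return out.getvalue()


def render(commands: Sequence[DrawCommand], backend: str, sink: IO) -> None:
    """Render commands with ``backend`` ('svg' or 'tex') into ``sink``.

    ``sink`` may be a text or binary file object; output is
    byte-deterministic for fixed input.
    """
    if backend == "svg":
        doc = render_svg(commands)
    elif backend == "tex":
        doc = render_tex(commands)
    else:
        raise ValueError(f"unknown backend {backend!r}; expected one of {', '.join(BACKENDS)}")
    try:
        sink.write(doc)
    except TypeError:
        sink.write(doc.encode("utf-8"))
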