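"""Rendering of the box chart: SVG and plain-text output.

Each parameter occupies a row of nine cells; cells 4-6 sit on a shared
grey rectangle (the normal range) and one marker shows where the
patient's value fell.  The renderer draws exactly what the classifier
decided — it never re-derives the box from the value.
"""

from __future__ import annotations

import enum
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Mapping

from .boxbuilder import BoxLimits
from .classify import CardioboxProfile, OutOfRange
from .errors import InvalidInputError, RenderError
from .params import DISPLAY_ORDER, Parameter

SVG_NS = "http://www.w3.org/2000/svg"


class MarkerStyle(str, enum.Enum):
    DOT = "DOT"
    CROSS = "CROSS"


@dataclass(frozen=True)
class RenderSpec:
    """Geometry and styling of the chart (abstract drawing units)."""

    rows: tuple[Parameter, ...] = DISPLAY_ORDER
    show_labels: bool = True
    show_bounds: bool = False
    marker_style: MarkerStyle = MarkerStyle.DOT
    cell_width: float = 64.0
    cell_height: float = 30.0
    padding: float = 8.0
    label_width: float = 70.0
    grey: str = "#D3D3D3"
    proportional: bool = False
    render_empty: bool = False

    def __post_init__(self) -> None:
        if not self.rows:
            raise InvalidInputError("RenderSpec needs at least one row")
        if min(self.cell_width, self.cell_height) <= 0 or self.padding < 0:
            raise InvalidInputError("cell geometry must be positive")


def _marker_fraction(
    assignment, limits: BoxLimits, proportional: bool
) -> float:
    """Horizontal position of the marker within its cell, in [0, 1]."""
    if not proportional:
        return 0.5
    b = limits.boundaries
    k = assignment.box
    lo, hi = b[k - 1], b[k]
    frac = (assignment.value - lo) / (hi - lo)
    return min(max(frac, 0.0), 1.0)


def render_svg(
    profile: CardioboxProfile,
    limits_set: Mapping[Parameter, BoxLimits],
    spec: RenderSpec = RenderSpec(),
) -> str:
    """Draw the chart as an SVG 1.1 document (text)."""
    if not profile.assignments and not spec.render_empty:
        raise RenderError(
            "profile has no assignments; set RenderSpec.render_empty to draw the empty grid"
        )
    for a in profile.assignments:
        if a.parameter not in limits_set:
            raise InvalidInputError(f"no limits for {a.parameter.value}")

    rows = [p for p in spec.rows if any(a.parameter is p for a in profile.assignments)]
    if not rows and spec.render_empty:
        rows = list(spec.rows)

    left = spec.label_width if spec.show_labels else spec.padding
    top = spec.cell_height if spec.show_labels else spec.padding
    width = left + 9 * spec.cell_width + spec.padding
    height = top + len(rows) * (spec.cell_height + spec.padding) + spec.padding

    ET.register_namespace("", SVG_NS)
    svg = ET.Element(
        f"{{{SVG_NS}}}svg",
        {
            "width": str(width),
            "height": str(height),
            "viewBox": f"0 0 {width} {height}",
            "version": "1.1",
        },
    )

    def cell_x(box: int) -> float:
        return left + (box - 1) * spec.cell_width

    if spec.show_labels:
        for box in range(1, 10):
            label = ET.SubElement(
                svg,
                f"{{{SVG_NS}}}text",
                {
                    "x": str(cell_x(box) + spec.cell_width / 2),
                    "y": str(top - spec.padding),
                    "text-anchor": "middle",
                    "class": "box-label",
                    "font-size": "12",
                },
            )
            label.text = str(box)

    for row_idx, param in enumerate(rows):
        y = top + row_idx * (spec.cell_height + spec.padding)
        limits = limits_set[param]

        if spec.show_labels:
            text = ET.SubElement(
                svg,
                f"{{{SVG_NS}}}text",
                {
                    "x": str(left - spec.padding),
                    "y": str(y + spec.cell_height * 0.65),
                    "text-anchor": "end",
                    "class": "param-label",
                    "font-size": "12",
                },
            )
            text.text = param.normalized_name

        # grey normal-range backdrop spanning cells 4-6, behind the outlines
        ET.SubElement(
            svg,
            f"{{{SVG_NS}}}rect",
            {
                "x": str(cell_x(4)),
                "y": str(y),
                "width": str(3 * spec.cell_width),
                "height": str(spec.cell_height),
                "fill": spec.grey,
                "class": "normal-zone",
            },
        )
        for box in range(1, 10):
            ET.SubElement(
                svg,
                f"{{{SVG_NS}}}rect",
                {
                    "x": str(cell_x(box)),
                    "y": str(y),
                    "width": str(spec.cell_width),
                    "height": str(spec.cell_height),
                    "fill": "none",
                    "stroke": "black",
                    "class": "box",
                },
            )
            if spec.show_bounds:
                lo, hi = limits.displayed[box - 1]
                bound = ET.SubElement(
                    svg,
                    f"{{{SVG_NS}}}text",
                    {
                        "x": str(cell_x(box) + spec.cell_width / 2),
                        "y": str(y + spec.cell_height - 4),
                        "text-anchor": "middle",
                        "class": "bound-label",
                        "font-size": "8",
                    },
                )
                bound.text = f"{lo:.2f}–{hi:.2f}"

        try:
            assignment = profile.assignment(param)
        except KeyError:
            continue
        frac = _marker_fraction(assignment, limits, spec.proportional)
        mx = cell_x(assignment.box) + frac * spec.cell_width
        my = y + spec.cell_height / 2
        r = min(spec.cell_width, spec.cell_height) * 0.18
        if spec.marker_style is MarkerStyle.DOT:
            ET.SubElement(
                svg,
                f"{{{SVG_NS}}}circle",
                {"cx": str(mx), "cy": str(my), "r": str(r), "class": "marker"},
            )
        else:
            ET.SubElement(
                svg,
                f"{{{SVG_NS}}}path",
                {
                    "d": (
                        f"M {mx - r} {my - r} L {mx + r} {my + r} "
                        f"M {mx - r} {my + r} L {mx + r} {my - r}"
                    ),
                    "stroke": "black",
                    "stroke-width": "2",
                    "class": "marker",
                },
            )
        # clamped values get an arrow glyph at the grid edge
        if assignment.out_of_range is not OutOfRange.NONE:
            if assignment.out_of_range is OutOfRange.BELOW_MIN:
                tip, base = left - 2, left + r
            else:
                tip, base = left + 9 * spec.cell_width + 2, left + 9 * spec.cell_width - r
            ET.SubElement(
                svg,
                f"{{{SVG_NS}}}polygon",
                {
                    "points": f"{tip},{my} {base},{my - r} {base},{my + r}",
                    "class": "oor",
                },
            )

    return ET.tostring(svg, encoding="unicode", xml_declaration=True)


def render_text(profile: CardioboxProfile) -> str:
    """One fixed-width line per parameter; ``*`` marks the assigned cell.

    The grey normal zone (boxes 4-6) is delimited by braces; clamped
    values show ``<`` / ``>`` instead of ``*``.
    """
    name_w = max((len(p.normalized_name) for p in DISPLAY_ORDER), default=6)
    header = " " * (name_w + 1)
    for box in range(1, 10):
        cell = f" {box} "
        header += ("{" if box == 4 else "") + cell + ("}" if box == 6 else "")
    lines = [header]
    for a in profile.assignments:
        line = f"{a.parameter.normalized_name:>{name_w}} "
        for box in range(1, 10):
            if box == a.box:
                mark = {
                    OutOfRange.BELOW_MIN: "<",
                    OutOfRange.ABOVE_MAX: ">",
                    OutOfRange.NONE: "*",
                }[a.out_of_range]
            else:
                mark = " "
            line += ("{" if box == 4 else "") + f"[{mark}]" + ("}" if box == 6 else "")
        lines.append(line)
    return "\n".join(lines) + "\n"
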