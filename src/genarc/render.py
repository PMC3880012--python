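"""SVG rendering of the circular view, plus grid (tabular) exports.

The drawing, outermost to innermost:

* phenotype glyph ticks (outside the reference ring),
* chromosome arc bands with labels — stain-colored when the reference has
  a cytoband track, member-perimeter-colored for composite references,
* uploaded annotation rings in upload order (bar / histogram / heatmap),
* association edges as quadratic curves pulled toward the circle center,
  or bundle curves with width growing as log2(count + 1).

Edge stroke color precedence: an explicit per-edge color wins, then the
diverging weight colormap (green for positive weights, pink for negative,
neutral grey at zero), then a default grey for unweighted edges.

Rendering is a pure function of its inputs — no timestamps or random ids
are embedded — so identical inputs produce byte-identical SVG.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import IO, Sequence

from matplotlib.colors import LinearSegmentedColormap, to_hex

from . import __version__
from .assoc_io import AnnotationRingSpec
from .graph import (
    Association,
    AssociationSet,
    Bundle,
    DEFAULT_RENDER_LIMIT,
)
from .layout import (
    Arc,
    ArcMap,
    LayoutConfig,
    locus_to_angle,
    place_glyph,
    ring_radii,
)
from .reference import CompositeReference, Locus, Reference, Unmapped, translate_label

__all__ = [
    "SvgDocument",
    "render_circular",
    "render_annotation_ring",
    "render_grid",
    "render_grid_html",
    "export_svg",
    "weight_color",
]

# Giemsa stain fills for the cytoband reference ring (grey ramp, red acen).
STAIN_PALETTE = {
    "gneg": "#ffffff",
    "gpos25": "#c8c8c8",
    "gpos50": "#969696",
    "gpos75": "#646464",
    "gpos100": "#323232",
    "gvar": "#dcdcdc",
    "stalk": "#6699cc",
    "acen": "#cc3333",
}
DEFAULT_BAND_FILL = "#d9d9d9"
DEFAULT_EDGE_COLOR = "#808080"

# Diverging weight colormap: pink (negative) - neutral grey (zero) - green
# (positive), matching the correlation-edge color convention.
_WEIGHT_CMAP = LinearSegmentedColormap.from_list(
    "pink-grey-green", ["#d01c8b", "#bdbdbd", "#4dac26"]
)
_HEAT_CMAP = LinearSegmentedColormap.from_list(
    "heat-blue-red", ["#2166ac", "#f7f7f7", "#b2182b"]
)


def weight_color(weight: float, vmax: float) -> str:
    """Hex color for a weight on the symmetric [-vmax, +vmax] scale."""
    if vmax <= 0 or weight == 0:
        return to_hex(_WEIGHT_CMAP(0.5))
    x = max(-1.0, min(1.0, weight / vmax))
    return to_hex(_WEIGHT_CMAP(0.5 + 0.5 * x))


def _fmt(x: float) -> str:
    return f"{x:.3f}"


@dataclass
class SvgDocument:
    """A built SVG drawing with element-count introspection helpers."""

    root: ET.Element

    def tostring(self) -> bytes:
        tree = ET.ElementTree(self.root)
        ET.indent(tree, space="  ")
        return ET.tostring(self.root, encoding="utf-8", xml_declaration=True)

    def count_class(self, css_class: str) -> int:
        return sum(
            1
            for el in self.root.iter()
            if css_class in (el.get("class") or "").split()
        )

    def elements_of_class(self, css_class: str) -> list[ET.Element]:
        return [
            el
            for el in self.root.iter()
            if css_class in (el.get("class") or "").split()
        ]


class _Canvas:
    """Coordinate bookkeeping shared by the drawing helpers."""

    def __init__(self, config: LayoutConfig):
        self.config = config
        margin = 40.0
        self.size = 2.0 * (config.glyph_radius + margin)
        self.center = (self.size / 2.0, self.size / 2.0)

    def xy(self, sweep_deg: float, radius: float) -> tuple[float, float]:
        return self.config.to_xy(sweep_deg, radius, self.center)


def _arc_points(canvas: _Canvas, a0: float, a1: float, radius: float,
                max_step: float = 3.0) -> list[tuple[float, float]]:
    """Sample an arc densely enough for smooth polyline approximation."""
    span = a1 - a0
    steps = max(2, int(abs(span) / max_step) + 1)
    return [
        canvas.xy(a0 + span * i / steps, radius) for i in range(steps + 1)
    ]


def _annular_sector(canvas: _Canvas, a0: float, a1: float,
                    r_in: float, r_out: float) -> str:
    outer = _arc_points(canvas, a0, a1, r_out)
    inner = _arc_points(canvas, a1, a0, r_in)
    cmds = [f"M {_fmt(outer[0][0])},{_fmt(outer[0][1])}"]
    cmds += [f"L {_fmt(x)},{_fmt(y)}" for x, y in outer[1:]]
    cmds += [f"L {_fmt(x)},{_fmt(y)}" for x, y in inner]
    cmds.append("Z")
    return " ".join(cmds)


def _edge_path(canvas: _Canvas, angle_a: float, angle_b: float) -> str:
    """Quadratic chord whose control point sits toward the circle center.

    The control point lies on the ray from the center through the chord
    midpoint, at 0.2 of the edge radius, pulling long-range edges through
    the middle of the disc.
    """
    r = canvas.config.edge_radius
    x0, y0 = canvas.xy(angle_a, r)
    x1, y1 = canvas.xy(angle_b, r)
    cx, cy = canvas.center
    mx, my = (x0 + x1) / 2.0 - cx, (y0 + y1) / 2.0 - cy
    norm = (mx * mx + my * my) ** 0.5
    if norm < 1e-9:  # diametric chord: control point at the center
        qx, qy = cx, cy
    else:
        k = 0.2 * r / norm
        qx, qy = cx + mx * k, cy + my * k
    return (
        f"M {_fmt(x0)},{_fmt(y0)} Q {_fmt(qx)},{_fmt(qy)} "
        f"{_fmt(x1)},{_fmt(y1)}"
    )


def _chrom_band_elements(
    canvas: _Canvas,
    arc: Arc,
    band: tuple[float, float],
    reference: Reference,
) -> list[ET.Element]:
    r_in, r_out = band
    els: list[ET.Element] = []
    fill = DEFAULT_BAND_FILL
    if isinstance(reference, CompositeReference):
        fill = reference.member_color(arc.chrom) or fill
    base = ET.Element(
        "path",
        {
            "class": "chrom-band",
            "d": _annular_sector(canvas, arc.start_deg, arc.end_deg, r_in, r_out),
            "fill": fill,
            "stroke": "#333333",
            "stroke-width": "0.8",
            "data-chrom": arc.chrom,
        },
    )
    els.append(base)
    # stain-colored sub-bands when a cytoband track exists
    if not isinstance(reference, CompositeReference):
        for bandrec in reference.cytobands:
            if bandrec.locus.chrom != arc.chrom:
                continue
            frac0 = (bandrec.locus.start - 1) / arc.length_bp
            frac1 = bandrec.locus.end / arc.length_bp
            a0 = arc.start_deg + frac0 * arc.span_deg
            a1 = arc.start_deg + frac1 * arc.span_deg
            els.append(
                ET.Element(
                    "path",
                    {
                        "class": "cytoband",
                        "d": _annular_sector(canvas, a0, a1, r_in, r_out),
                        "fill": STAIN_PALETTE.get(bandrec.stain_class, DEFAULT_BAND_FILL),
                        "stroke": "none",
                        "data-band": bandrec.band_name,
                    },
                )
            )
    mid = (arc.start_deg + arc.end_deg) / 2.0
    lx, ly = canvas.xy(mid, r_out + 14.0)
    label = ET.Element(
        "text",
        {
            "class": "chrom-label",
            "x": _fmt(lx),
            "y": _fmt(ly),
            "font-size": "11",
            "font-family": "sans-serif",
            "text-anchor": "middle",
        },
    )
    label.text = arc.chrom
    els.append(label)
    return els


def _resolve_ring_target(
    target: str, reference: Reference
) -> Locus | Unmapped:
    return translate_label(target, reference)


def render_annotation_ring(
    ringspec: AnnotationRingSpec,
    band: tuple[float, float],
    arcmap: ArcMap,
    reference: Reference,
    config: LayoutConfig | None = None,
    canvas: _Canvas | None = None,
) -> tuple[list[ET.Element], list[str]]:
    """Draw one annotation ring into a radial band.

    Returns (elements, skipped targets).  Bar rings draw a radial bar per
    entry with extent proportional to |value| / max|value|; histogram
    rings share a mid-band baseline with positive values growing outward
    and negative inward; heatmap rings fill each entry's genomic span with
    a color from the value colormap (or the entry's own color for
    color-typed rings).
    """
    if canvas is None:
        canvas = _Canvas(config or LayoutConfig())
    r_in, r_out = band
    thickness = r_out - r_in
    mid_r = (r_in + r_out) / 2.0
    values = ringspec.values
    vmax = max((abs(v) for v in values), default=0.0)
    vlo = min(values, default=0.0)
    vhi = max(values, default=0.0)
    els: list[ET.Element] = []
    skipped: list[str] = []
    frame = ET.Element(
        "circle",
        {
            "class": "ring-frame",
            "cx": _fmt(canvas.center[0]),
            "cy": _fmt(canvas.center[1]),
            "r": _fmt(mid_r),
            "fill": "none",
            "stroke": "#cccccc",
            "stroke-width": "0.5",
        },
    )
    els.append(frame)
    for target, value, color in ringspec.entries:
        locus = _resolve_ring_target(target, reference)
        if isinstance(locus, Unmapped):
            skipped.append(target)
            continue
        arc = arcmap[locus.chrom]
        if ringspec.style == "heatmap":
            frac0 = (locus.start - 1) / arc.length_bp
            frac1 = locus.end / arc.length_bp
            a0 = arc.start_deg + frac0 * arc.span_deg
            a1 = arc.start_deg + frac1 * arc.span_deg
            if color is None:
                x = 0.5 if vhi == vlo else (value - vlo) / (vhi - vlo)
                color = to_hex(_HEAT_CMAP(x))
            els.append(
                ET.Element(
                    "path",
                    {
                        "class": "ring-cell",
                        "d": _annular_sector(canvas, a0, a1, r_in, r_out),
                        "fill": color,
                        "stroke": "none",
                        "data-target": target,
                    },
                )
            )
            continue
        angle = locus_to_angle(locus, arcmap)
        frac = 0.0 if vmax == 0 else abs(value) / vmax
        if ringspec.style == "bar":
            x0, y0 = canvas.xy(angle, r_in)
            x1, y1 = canvas.xy(angle, r_in + frac * thickness)
            cls, stroke = "ring-bar", "#2b5d8a"
        else:  # histogram
            half = thickness / 2.0
            extent = frac * half
            if value >= 0:
                x0, y0 = canvas.xy(angle, mid_r)
                x1, y1 = canvas.xy(angle, mid_r + extent)
                stroke = "#2ca02c"
            else:
                x0, y0 = canvas.xy(angle, mid_r)
                x1, y1 = canvas.xy(angle, mid_r - extent)
                stroke = "#d62728"
            cls = "ring-hist"
        els.append(
            ET.Element(
                "line",
                {
                    "class": cls,
                    "x1": _fmt(x0),
                    "y1": _fmt(y0),
                    "x2": _fmt(x1),
                    "y2": _fmt(y1),
                    "stroke": stroke,
                    "stroke-width": "1.6",
                    "data-target": target,
                },
            )
        )
    return els, skipped


def render_circular(
    aset: AssociationSet,
    arcmap: ArcMap,
    config: LayoutConfig,
    reference: Reference,
    rings: Sequence[AnnotationRingSpec] = (),
    bundles: tuple[list[Bundle], list[Association]] | None = None,
    render_limit: int = DEFAULT_RENDER_LIMIT,
) -> SvgDocument:
    """Render the circular view.

    When ``bundles`` (the output of :func:`genarc.graph.bundle`) is given,
    bundle curves plus passthrough edges are drawn instead of individual
    edges.  The render limit truncates the drawn curves — never the
    underlying set — to the first ``render_limit`` in input order.
    """
    canvas = _Canvas(config)
    root = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": _fmt(canvas.size),
            "height": _fmt(canvas.size),
            "viewBox": f"0 0 {_fmt(canvas.size)} {_fmt(canvas.size)}",
        },
    )
    meta = ET.SubElement(root, "metadata")
    provenance = "; ".join(aset.provenance) if aset.provenance else "unfiltered"
    meta.text = f"genarc {__version__} | provenance: {provenance} | limit: {render_limit}"

    bands = ring_radii(len(rings), config)

    g_chrom = ET.SubElement(root, "g", {"class": "chromosomes"})
    for arc in arcmap.arcs:
        for el in _chrom_band_elements(canvas, arc, bands[0], reference):
            g_chrom.append(el)

    g_rings = ET.SubElement(root, "g", {"class": "rings"})
    for i, ringspec in enumerate(rings):
        ring_g = ET.SubElement(g_rings, "g", {"class": f"ring ring-{i}"})
        els, skipped = render_annotation_ring(
            ringspec, bands[i + 1], arcmap, reference, canvas=canvas
        )
        if len(skipped) == len(ringspec.entries):
            g_rings.remove(ring_g)  # nothing resolvable: skip whole ring
            continue
        for el in els:
            ring_g.append(el)

    # --- edge curves (respecting the render limit) ---
    g_edges = ET.SubElement(root, "g", {"class": "edges"})
    if bundles is None:
        curves: list[tuple[str, Association | Bundle]] = [
            ("edge", e) for e in aset.drawable_edges()
        ]
    else:
        bundle_list, passthrough = bundles
        curves = [("bundle", b) for b in bundle_list] + [
            ("edge", e) for e in passthrough
        ]
    curves = curves[:render_limit]
    weights = [
        item.weight
        for kind, item in curves
        if kind == "edge" and item.weight is not None and item.color is None
    ]
    vmax = max((abs(w) for w in weights), default=0.0)
    for kind, item in curves:
        if kind == "edge":
            angle_a = locus_to_angle(item.a.locus, arcmap)
            angle_b = locus_to_angle(item.b.locus, arcmap)
            if item.color is not None:
                stroke = item.color
            elif item.weight is not None:
                stroke = weight_color(item.weight, vmax)
            else:
                stroke = DEFAULT_EDGE_COLOR
            attrs = {
                "class": "edge",
                "d": _edge_path(canvas, angle_a, angle_b),
                "fill": "none",
                "stroke": stroke,
                "stroke-width": "1.0",
                "stroke-opacity": "0.75",
            }
            if item.weight is not None:
                attrs["data-weight"] = repr(item.weight)
            el = ET.Element("path", attrs)
            g_edges.append(el)
            for node in (item.a, item.b):
                if node.source_type:
                    angle = locus_to_angle(node.locus, arcmap)
                    nx, ny = canvas.xy(angle, config.edge_radius)
                    g_edges.append(
                        ET.Element(
                            "circle",
                            {
                                "class": "node-dot",
                                "cx": _fmt(nx),
                                "cy": _fmt(ny),
                                "r": "2.2",
                                "fill": config.type_palette.get(
                                    node.source_type, config.type_palette["none"]
                                ),
                            },
                        )
                    )
        else:  # bundle
            first = item.members[0]
            angle_a = locus_to_angle(first.a.locus, arcmap)
            angle_b = locus_to_angle(first.b.locus, arcmap)
            width = 1.0 * math.log2(item.count + 1)
            g_edges.append(
                ET.Element(
                    "path",
                    {
                        "class": "bundle",
                        "d": _edge_path(canvas, angle_a, angle_b),
                        "fill": "none",
                        "stroke": DEFAULT_EDGE_COLOR,
                        "stroke-width": _fmt(width),
                        "stroke-opacity": "0.6",
                        "data-count": str(item.count),
                    },
                )
            )

    # --- phenotype glyph ticks ---
    g_glyphs = ET.SubElement(root, "g", {"class": "glyphs"})
    for edge in aset.glyph_edges():
        angle, radius = place_glyph(edge, arcmap, config)
        x0, y0 = canvas.xy(angle, radius - config.glyph_length)
        x1, y1 = canvas.xy(angle, radius)
        g_glyphs.append(
            ET.Element(
                "line",
                {
                    "class": "glyph",
                    "x1": _fmt(x0),
                    "y1": _fmt(y0),
                    "x2": _fmt(x1),
                    "y2": _fmt(y1),
                    "stroke": config.type_palette["PHENO"],
                    "stroke-width": "2.0",
                },
            )
        )
    return SvgDocument(root=root)


GRID_COLUMNS = (
    "label_a", "type_a", "locus_a",
    "label_b", "type_b", "locus_b",
    "weight", "color",
)


def _grid_rows(aset: AssociationSet) -> list[list[str]]:
    rows = []
    for e in aset.edges:
        rows.append([
            e.a.label,
            e.a.source_type or "",
            str(e.a.locus) if e.a.mapped else "unmapped",
            e.b.label,
            e.b.source_type or "",
            str(e.b.locus) if e.b.mapped else "unmapped",
            repr(e.weight) if e.weight is not None else "",
            e.color or "",
        ])
    return rows


def render_grid(aset: AssociationSet) -> str:
    """Grid view as TSV: one row per edge, input order preserved."""
    lines = ["\t".join(GRID_COLUMNS)]
    lines += ["\t".join(row) for row in _grid_rows(aset)]
    return "\n".join(lines) + "\n"


def render_grid_html(aset: AssociationSet) -> str:
    """Grid view as a standalone HTML table (human-readable export)."""
    def esc(s: str) -> str:
        return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")

    head = "".join(f"<th>{c}</th>" for c in GRID_COLUMNS)
    body = "".join(
        "<tr>" + "".join(f"<td>{esc(c)}</td>" for c in row) + "</tr>"
        for row in _grid_rows(aset)
    )
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\"/>"
        "<title>association grid</title></head><body>\n"
        f"<table border=\"1\"><thead><tr>{head}</tr></thead>"
        f"<tbody>{body}</tbody></table>\n</body></html>\n"
    )


def export_svg(doc: SvgDocument, path_or_stream: str | IO[bytes]) -> None:
    """Write the SVG document; identical inputs yield identical bytes."""
    data = doc.tostring()
    if isinstance(path_or_stream, str):
        with open(path_or_stream, "wb") as fh:
            fh.write(data)
    else:
        path_or_stream.write(data)
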