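"""Circular geometry: chromosome arcs, angles, ring radii, glyph placement.

Chromosomes are laid out as circumference segments in reference order,
starting at 12 o'clock and running clockwise.  Each chromosome's angular
span is proportional to its base-pair length: with ``n`` chromosomes and a
fixed inter-chromosome gap ``g`` degrees, chromosome ``i`` spans

    span_i = (360 - n*g) * length_i / genome_length

Angles here are expressed as *sweep* degrees: 0 at the start angle,
increasing along the drawing direction, so proportionality and
conservation statements are direction-agnostic.  The renderer converts
sweep degrees to canvas x/y.

Radially, the reference (cytoband / perimeter) ring sits outermost,
uploaded annotation rings stack inward in upload order, association edges
occupy the inner disc, and phenotype glyph ticks sit outside everything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .graph import Association
from .reference import Locus, Reference

__all__ = [
    "LayoutConfig",
    "Arc",
    "ArcMap",
    "LayoutError",
    "DEFAULT_TYPE_PALETTE",
    "build_arcmap",
    "locus_to_angle",
    "ring_radii",
    "place_glyph",
]


class LayoutError(ValueError):
    """Inconsistent layout configuration."""


# Node/glyph color encoding for omics source types.  The palette is a fixed,
# documented choice: genotype blue, expression orange, proteomics violet,
# phenotype dark red, untyped slate grey.
DEFAULT_TYPE_PALETTE: Mapping[str, str] = {
    "GENO": "#1f77b4",
    "GEXP": "#ff7f0e",
    "PROT": "#9467bd",
    "PHENO": "#8b0000",
    "none": "#556677",
}


@dataclass(frozen=True)
class LayoutConfig:
    """Geometry and styling knobs for the circular view.

    Radii are unitless canvas units (the SVG viewBox is sized to fit
    ``glyph_radius`` plus a margin).
    """

    gap_deg: float = 1.0
    start_angle_deg: float = 90.0  # 12 o'clock in math convention
    clockwise: bool = True
    radius_outer: float = 400.0   # outer edge of the reference ring
    ring_thickness: float = 18.0
    ring_spacing: float = 4.0
    edge_radius: float = 250.0    # edge chords attach at this radius
    glyph_radius: float = 420.0   # phenotype ticks, outside the reference ring
    glyph_length: float = 12.0
    weight_colormap: str = "pink-grey-green"  # diverging, zero = neutral grey
    type_palette: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PALETTE)
    )

    def __post_init__(self) -> None:
        if not (self.glyph_radius > self.radius_outer > self.edge_radius > 0):
            raise LayoutError(
                "radii must be strictly ordered glyph_radius > radius_outer "
                "> edge_radius > 0"
            )
        if self.gap_deg < 0:
            raise LayoutError("gap_deg must be >= 0")

    def to_xy(self, sweep_deg: float, radius: float,
              center: tuple[float, float]) -> tuple[float, float]:
        """Convert (sweep angle, radius) to canvas coordinates.

        Sweep 0 lies at ``start_angle_deg`` (math convention, y up);
        canvas y grows downward, so clockwise-on-screen means decreasing
        math angle.
        """
        sign = -1.0 if self.clockwise else 1.0
        phi = math.radians(self.start_angle_deg + sign * sweep_deg)
        cx, cy = center
        return (cx + radius * math.cos(phi), cy - radius * math.sin(phi))


@dataclass(frozen=True)
class Arc:
    """One chromosome's angular interval, in sweep degrees."""

    chrom: str
    length_bp: int
    start_deg: float
    end_deg: float

    @property
    def span_deg(self) -> float:
        return self.end_deg - self.start_deg


@dataclass(frozen=True)
class ArcMap:
    """Chromosome → angular interval assignment for one reference."""

    arcs: tuple[Arc, ...]
    genome_length: int
    gap_deg: float

    @property
    def usable_deg(self) -> float:
        return 360.0 - len(self.arcs) * self.gap_deg

    def __getitem__(self, chrom: str) -> Arc:
        for arc in self.arcs:
            if arc.chrom == chrom:
                return arc
        raise KeyError(f"chromosome {chrom!r} not in arc map")

    def __contains__(self, chrom: str) -> bool:
        return any(a.chrom == chrom for a in self.arcs)


def build_arcmap(reference: Reference, config: LayoutConfig) -> ArcMap:
    """Assign each chromosome its length-proportional arc.

    Chromosomes appear in reference order starting at sweep 0, separated
    by ``gap_deg``; a trailing gap closes the circle back to the start.
    """
    chroms = list(reference.chromosomes)
    n = len(chroms)
    usable = 360.0 - n * config.gap_deg
    if usable <= 0:
        raise LayoutError(
            f"{n} chromosomes x {config.gap_deg} degree gaps leave no usable "
            "circumference; reduce gap_deg"
        )
    total = sum(c.length_bp for c in chroms)
    arcs: list[Arc] = []
    cursor = 0.0
    for c in chroms:
        span = usable * c.length_bp / total
        arcs.append(Arc(c.name, c.length_bp, cursor, cursor + span))
        cursor += span + config.gap_deg
    return ArcMap(arcs=tuple(arcs), genome_length=total, gap_deg=config.gap_deg)


def locus_to_angle(locus: Locus, arcmap: ArcMap) -> float:
    """Sweep angle (degrees) of a locus midpoint.

    The midpoint base ``m`` maps to fraction ``(m - 0.5) / length`` of the
    chromosome's arc — base centers, so base 1 sits half a base-width in
    from the arc start and base ``length`` half a base-width before its
    end.  Strictly increasing in position; never lands inside a gap.
    """
    try:
        arc = arcmap[locus.chrom]
    except KeyError:
        raise LayoutError(f"locus {locus} references a chromosome missing "
                          "from the arc map") from None
    m = locus.midpoint
    if not 1 <= m <= arc.length_bp:
        raise LayoutError(f"locus {locus} midpoint {m} outside chromosome "
                          f"(1..{arc.length_bp})")
    frac = (m - 0.5) / arc.length_bp
    return arc.start_deg + frac * arc.span_deg


def ring_radii(n_uploaded_rings: int, config: LayoutConfig) -> list[tuple[float, float]]:
    """Radial bands (r_inner, r_outer), outermost (reference ring) first.

    Uploaded rings stack inward in upload order; everything must stay
    outside ``edge_radius`` where the association chords live.
    """
    if n_uploaded_rings < 0:
        raise LayoutError("n_uploaded_rings must be >= 0")
    bands: list[tuple[float, float]] = []
    outer = config.radius_outer
    for _ in range(n_uploaded_rings + 1):  # +1: the reference ring itself
        inner = outer - config.ring_thickness
        bands.append((inner, outer))
        outer = inner - config.ring_spacing
    if bands[-1][0] <= config.edge_radius:
        raise LayoutError(
            f"{n_uploaded_rings} rings reach radius {bands[-1][0]:.1f}, inside "
            f"edge_radius {config.edge_radius}; use thinner rings or a larger "
            "radius_outer"
        )
    return bands


def place_glyph(
    edge: Association, arcmap: ArcMap, config: LayoutConfig
) -> tuple[float, float]:
    """(sweep angle, radius) for a phenotype tick glyph.

    The tick marks the *mapped* endpoint's genomic position, drawn outside
    the reference ring in the PHENO palette color.  Requires exactly one
    mapped endpoint; an edge with no mapped endpoint cannot be placed.
    """
    mapped = [n for n in (edge.a, edge.b) if n.mapped]
    if len(mapped) != 1:
        raise LayoutError(
            "glyph placement needs exactly one mapped endpoint "
            f"(got {len(mapped)} for {edge.a.label} - {edge.b.label})"
        )
    angle = locus_to_angle(mapped[0].locus, arcmap)
    return angle, config.glyph_radius
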