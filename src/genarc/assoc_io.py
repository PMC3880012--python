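"""Parsers and writers for association edge lists and annotation rings.

Four input dialects are supported, selected by file extension:

========  =========  =====================================================
ext       delimiter  line form
========  =========  =====================================================
``.txt``  spaces     ``labelA labelB [weight-or-color]``
``.tsv``  tabs       ``labelA<TAB>labelB[<TAB>weight-or-color]``
``.csv``  commas     ``labelA,labelB[,weight-or-color]``
``.sif``  spaces     ``labelA relation labelB [more targets...]`` plus an
                     extended form with a trailing weight or color column
========  =========  =====================================================

The optional trailing column is a *weight* when it parses as a finite real
number, a *color* when it is a hex ``#rgb``/``#rrggbb`` string or a CSS
named color, and (in plain SIF only) an additional interaction target
otherwise.  A node label may carry an omics source-type suffix
``label^TYPE`` with TYPE in {GENO, GEXP, PROT, PHENO}; PHENO marks a
feature with no genomic coordinates (a phenotype or disease state).

Comment lines starting with ``#`` and blank lines are skipped everywhere.
Writers emit text that the corresponding parsers accept unchanged, so a
filtered export is a valid future input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import IO, Iterable, Iterator, Sequence

from matplotlib.colors import CSS4_COLORS

__all__ = [
    "EdgeRecord",
    "Dialect",
    "AnnotationRingSpec",
    "AssociationParseError",
    "DIALECTS",
    "SOURCE_TYPES",
    "RING_STYLES",
    "detect_dialect",
    "parse_associations",
    "parse_associations_path",
    "parse_sif",
    "parse_inline_edges",
    "parse_annotation_ring",
    "write_associations_tsv",
    "write_network_sif",
    "is_color",
]

SOURCE_TYPES = ("GENO", "GEXP", "PROT", "PHENO")
RING_STYLES = ("bar", "histogram", "heatmap")

_HEX_COLOR_RE = re.compile(r"^#([0-9a-fA-F]{3}|[0-9a-fA-F]{6})$")


class AssociationParseError(ValueError):
    """Malformed association / ring input, with file line context."""


@dataclass(frozen=True)
class EdgeRecord:
    """One parsed association line: two labelled endpoints plus options."""

    label_a: str
    label_b: str
    type_a: str | None = None
    type_b: str | None = None
    relation: str | None = None
    weight: float | None = None
    color: str | None = None
    line_no: int | None = None

    def __post_init__(self) -> None:
        if not self.label_a or not self.label_b:
            raise AssociationParseError("edge labels must be non-empty")
        if self.weight is not None and self.color is not None:
            raise AssociationParseError(
                "an edge carries either a weight or a color, not both"
            )

    def key(self) -> tuple:
        """Multiset identity used by round-trip checks (line_no ignored)."""
        return (self.label_a, self.type_a, self.label_b, self.type_b,
                self.weight, self.color)


@dataclass(frozen=True)
class Dialect:
    name: str
    delimiter: str | None  # None = any whitespace run
    supports_multi_target: bool = False


DIALECTS: dict[str, Dialect] = {
    ".txt": Dialect("space", None),
    ".tsv": Dialect("tab", "\t"),
    ".csv": Dialect("comma", ","),
    ".sif": Dialect("sif", None, supports_multi_target=True),
}


def detect_dialect(filename: str) -> Dialect:
    """Map a filename extension to its input dialect."""
    dot = filename.rfind(".")
    ext = filename[dot:].lower() if dot >= 0 else ""
    try:
        return DIALECTS[ext]
    except KeyError:
        supported = ", ".join(sorted(DIALECTS))
        raise AssociationParseError(
            f"unsupported file extension {ext!r} for {filename!r}; "
            f"supported: {supported}"
        ) from None


def is_color(token: str) -> bool:
    """True for hex ``#rgb``/``#rrggbb`` or a CSS/HTML named color."""
    return bool(_HEX_COLOR_RE.match(token)) or token.strip().lower() in CSS4_COLORS


def _as_number(token: str) -> float | None:
    try:
        value = float(token)
    except ValueError:
        return None
    return value if value == value and abs(value) != float("inf") else None


def _split_type(label: str) -> tuple[str, str | None]:
    """Strip a trailing ``^TYPE`` source-type suffix when TYPE is known."""
    if "^" in label:
        base, _, suffix = label.rpartition("^")
        if suffix.upper() in SOURCE_TYPES and base:
            return base, suffix.upper()
    return label, None


def _data_lines(stream: IO[str] | Iterable[str]) -> Iterator[tuple[int, str]]:
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\r\n").strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def _record_from_fields(
    fields: Sequence[str], lineno: int, source: str
) -> EdgeRecord:
    if len(fields) < 2 or len(fields) > 3:
        raise AssociationParseError(
            f"{source}:{lineno}: expected 2 or 3 fields "
            f"(labelA, labelB[, weight-or-color]), got {len(fields)}"
        )
    label_a, type_a = _split_type(fields[0].strip())
    label_b, type_b = _split_type(fields[1].strip())
    weight = color = None
    if len(fields) == 3:
        extra = fields[2].strip()
        weight = _as_number(extra)
        if weight is None:
            if not is_color(extra):
                raise AssociationParseError(
                    f"{source}:{lineno}: trailing column {extra!r} is neither "
                    "a number nor an HTML color"
                )
            color = extra
    if not label_a or not label_b:
        raise AssociationParseError(f"{source}:{lineno}: empty node label")
    return EdgeRecord(label_a, label_b, type_a, type_b,
                      weight=weight, color=color, line_no=lineno)


def parse_associations(
    stream: IO[str] | Iterable[str],
    dialect: Dialect,
    source: str = "<stream>",
) -> list[EdgeRecord]:
    """Parse a delimited edge list (or SIF, dispatching on the dialect)."""
    if dialect.supports_multi_target:
        return parse_sif(stream, source)
    records: list[EdgeRecord] = []
    for lineno, line in _data_lines(stream):
        if dialect.delimiter is None:
            fields = line.split()
        else:
            fields = [f.strip() for f in line.split(dialect.delimiter)]
        records.append(_record_from_fields(fields, lineno, source))
    return records


def parse_associations_path(path: str) -> list[EdgeRecord]:
    """Parse an edge-list file, detecting the dialect from its extension."""
    dialect = detect_dialect(path)
    with open(path, encoding="utf-8") as fh:
        return parse_associations(fh, dialect, source=path)


def parse_sif(stream: IO[str] | Iterable[str], source: str = "<stream>") -> list[EdgeRecord]:
    """Parse (extended) Simple Interaction Format.

    ``A rel B C D`` expands to one record per target.  A 4-field line whose
    last token is a finite number is the extended weighted form, a
    recognized HTML color is the extended colored form, and anything else
    is a second target of a plain multi-target line.  Weights/colors on
    multi-target lines (>= 5 fields) are not permitted.
    """
    records: list[EdgeRecord] = []
    for lineno, line in _data_lines(stream):
        fields = line.split()
        if len(fields) < 3:
            raise AssociationParseError(
                f"{source}:{lineno}: SIF needs at least 'source relation target'"
            )
        src_label, type_a = _split_type(fields[0])
        relation = fields[1]
        weight = color = None
        targets = fields[2:]
        if len(fields) == 4:
            weight = _as_number(fields[3])
            if weight is not None:
                targets = fields[2:3]
            elif is_color(fields[3]):
                color = fields[3]
                targets = fields[2:3]
        for target in targets:
            label_b, type_b = _split_type(target)
            records.append(
                EdgeRecord(src_label, label_b, type_a, type_b,
                           relation=relation, weight=weight, color=color,
                           line_no=lineno)
            )
    return records


def parse_inline_edges(decl: str) -> list[EdgeRecord]:
    """Parse a compact inline edge declaration.

    Semicolon-separated items ``A,B[,weight-or-color]`` — handy for small
    test networks passed on the command line.
    """
    records: list[EdgeRecord] = []
    if not decl.strip():
        return records
    for idx, item in enumerate(decl.strip().split(";"), 1):
        item = item.strip()
        if not item:
            continue
        fields = [f.strip() for f in item.split(",")]
        try:
            rec = _record_from_fields(fields, idx, "<inline>")
        except AssociationParseError as exc:
            raise AssociationParseError(f"inline edge item {idx} ({item!r}): {exc}") from None
        records.append(replace(rec, line_no=idx))
    return records


@dataclass(frozen=True)
class AnnotationRingSpec:
    """A styled annotation track: (target, value) or (target, color) pairs.

    ``style`` is ``bar``, ``histogram`` or ``heatmap``.  A target is a gene
    label (resolved through the active reference's gene index) or a
    positional ``chr:start:end`` segment.  One ring holds either numeric
    values or explicit colors, never both.
    """

    style: str
    entries: tuple[tuple[str, float | None, str | None], ...]
    name: str = ""

    @property
    def is_color_ring(self) -> bool:
        return any(color is not None for _, _, color in self.entries)

    @property
    def values(self) -> list[float]:
        return [v for _, v, _ in self.entries if v is not None]


def parse_annotation_ring(
    stream: IO[str] | Iterable[str], source: str = "<stream>"
) -> AnnotationRingSpec:
    """Parse an annotation ring file.

    First non-blank line must be a ``#ring <style>`` header; data lines are
    ``target<TAB>value`` or ``target<TAB>color``.
    """
    style: str | None = None
    entries: list[tuple[str, float | None, str | None]] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\r\n").strip()
        if not line:
            continue
        if line.startswith("#"):
            if style is None:
                header = line.lstrip("#").strip().split()
                if len(header) != 2 or header[0].lower() != "ring":
                    raise AssociationParseError(
                        f"{source}:{lineno}: expected '#ring <style>' header"
                    )
                if header[1].lower() not in RING_STYLES:
                    raise AssociationParseError(
                        f"{source}:{lineno}: unknown ring style {header[1]!r}; "
                        f"supported: {', '.join(RING_STYLES)}"
                    )
                style = header[1].lower()
            continue
        if style is None:
            raise AssociationParseError(
                f"{source}:{lineno}: data before the '#ring <style>' header"
            )
        parts = line.split("\t") if "\t" in line else line.split()
        parts = [p.strip() for p in parts if p.strip()]
        if len(parts) != 2:
            raise AssociationParseError(
                f"{source}:{lineno}: expected 'target<TAB>value-or-color'"
            )
        target, payload = parts
        _validate_ring_target(target, lineno, source)
        value = _as_number(payload)
        if value is not None:
            entries.append((target, value, None))
        elif is_color(payload):
            entries.append((target, None, payload))
        else:
            raise AssociationParseError(
                f"{source}:{lineno}: {payload!r} is neither a number nor a color"
            )
    if style is None:
        raise AssociationParseError(f"{source}: missing '#ring <style>' header")
    if not entries:
        raise AssociationParseError(f"{source}: ring has no entries")
    has_values = any(v is not None for _, v, _ in entries)
    has_colors = any(c is not None for _, _, c in entries)
    if has_values and has_colors:
        raise AssociationParseError(
            f"{source}: ring mixes numeric values and explicit colors"
        )
    if has_colors and style != "heatmap":
        raise AssociationParseError(
            f"{source}: color-typed entries require the heatmap style"
        )
    return AnnotationRingSpec(style=style, entries=tuple(entries), name=source)


def _validate_ring_target(target: str, lineno: int, source: str) -> None:
    # positional segments must satisfy the 1-based inclusive coordinate rule
    from .reference import PositionLabelError, _POS_RE, parse_position_label

    if _POS_RE.match(target):
        try:
            parse_position_label(target)
        except PositionLabelError as exc:
            raise AssociationParseError(f"{source}:{lineno}: {exc}") from None


# ---------------------------------------------------------------------------
# writers

def _format_weight(weight: float) -> str:
    return repr(weight)  # shortest decimal string that round-trips exactly


def _label(label: str, type_: str | None) -> str:
    return f"{label}^{type_}" if type_ else label


def write_associations_tsv(records: Iterable[EdgeRecord], stream: IO[str]) -> None:
    """Write records as a ``.tsv`` edge list re-importable by the parser."""
    stream.write("# labelA\tlabelB\tweight-or-color\n")
    for rec in records:
        cols = [_label(rec.label_a, rec.type_a), _label(rec.label_b, rec.type_b)]
        if rec.weight is not None:
            cols.append(_format_weight(rec.weight))
        elif rec.color is not None:
            cols.append(rec.color)
        stream.write("\t".join(cols) + "\n")


def write_network_sif(records: Iterable[EdgeRecord], stream: IO[str]) -> None:
    """Write records as extended SIF (default relation ``assoc``)."""
    for rec in records:
        cols = [
            _label(rec.label_a, rec.type_a),
            rec.relation or "assoc",
            _label(rec.label_b, rec.type_b),
        ]
        if rec.weight is not None:
            cols.append(_format_weight(rec.weight))
        elif rec.color is not None:
            cols.append(rec.color)
        stream.write(" ".join(cols) + "\n")
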