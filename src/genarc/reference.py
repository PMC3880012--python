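"""Organism genome references and label-to-locus translation.

A reference is an ordered list of chromosomes with base-pair lengths, an
optional cytogenetic band track for the outer ring, and a pluggable gene
index mapping gene symbols / ENSEMBL ids / ENTREZ ids to loci.  References
come from three places:

* the built-in catalog of ten organisms shipped as static TSV tables
  (:func:`load_catalog`, :func:`get_reference`),
* user-defined custom organisms (:func:`define_custom_reference`), e.g. an
  organelle genome or an unsupported strain, and
* composites of several organisms on one circle
  (:func:`combine_references`) for between-organism association plots such
  as human-mouse ortholog networks.

Coordinates are 1-based and inclusive throughout: the positional node label
``chr12:100:200`` denotes bases 100..200 of chromosome 12, and
``chr1:5:5`` is a single base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence, Union

__all__ = [
    "Chromosome",
    "Locus",
    "Unmapped",
    "CytobandEntry",
    "OrganismReference",
    "CompositeReference",
    "ReferenceSpecError",
    "PositionLabelError",
    "load_catalog",
    "get_reference",
    "define_custom_reference",
    "combine_references",
    "parse_position_label",
    "translate_label",
    "load_gene_index",
    "read_chrom_table",
]


class ReferenceSpecError(ValueError):
    """Invalid reference definition or corrupted reference data file."""


class PositionLabelError(ValueError):
    """A label does not parse as the positional ``chr:start:end`` form."""


@dataclass(frozen=True)
class Chromosome:
    """One chromosome (or contig): a name and its length in base pairs."""

    name: str
    length_bp: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ReferenceSpecError("chromosome name must be non-empty")
        if self.length_bp < 1:
            raise ReferenceSpecError(
                f"chromosome {self.name!r}: length_bp must be >= 1, got {self.length_bp}"
            )


@dataclass(frozen=True)
class Locus:
    """A 1-based inclusive genomic interval ``chrom:start:end``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise PositionLabelError(
                f"invalid span {self.chrom}:{self.start}:{self.end} "
                "(need 1 <= start <= end)"
            )

    @property
    def midpoint(self) -> int:
        """Anchor base used for angular placement: floor((start+end)/2)."""
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # the positional label form
        return f"{self.chrom}:{self.start}:{self.end}"


@dataclass(frozen=True)
class Unmapped:
    """Marker for a label with no genomic coordinates, with the reason why."""

    reason: str = "label not recognized"

    def __bool__(self) -> bool:
        return False


@dataclass(frozen=True)
class CytobandEntry:
    """A stained band of the reference outer ring (e.g. Giemsa bands)."""

    locus: Locus
    band_name: str
    stain_class: str


# ENSEMBL ids (ENSG/ENSMUSG/FBgn-free Ensembl grammar) and all-digit ENTREZ
# ids are matched verbatim; everything else is treated as a gene symbol and
# matched case-insensitively.
_ID_RE = re.compile(r"^(ENS[A-Z]*\d{6,}(\.\d+)?|\d+)$")

_POS_RE = re.compile(r"^([^:|\s]+):(-?\d+):(-?\d+)$")


def _looks_like_id(label: str) -> bool:
    return bool(_ID_RE.match(label))


class _GeneIndex:
    """Label -> Locus mapping with symbol case-folding.

    Verbatim keys win; a case-folded lookup is attempted only for labels
    that do not look like ENSEMBL/ENTREZ identifiers.
    """

    def __init__(self, entries: Mapping[str, Locus] | None = None):
        self._exact: dict[str, Locus] = {}
        self._folded: dict[str, Locus] = {}
        if entries:
            for label, locus in entries.items():
                self.add(label, locus)

    def add(self, label: str, locus: Locus) -> None:
        label = label.strip()
        if not label:
            raise ReferenceSpecError("gene index labels must be non-empty")
        self._exact[label] = locus
        if not _looks_like_id(label):  # ids are matched verbatim only
            self._folded.setdefault(label.casefold(), locus)

    def get(self, label: str) -> Locus | None:
        label = label.strip()
        hit = self._exact.get(label)
        if hit is None and not _looks_like_id(label):
            hit = self._folded.get(label.casefold())
        return hit

    def __len__(self) -> int:
        return len(self._exact)

    def __contains__(self, label: str) -> bool:
        return self.get(label) is not None

    def items(self) -> Iterator[tuple[str, Locus]]:
        return iter(self._exact.items())


@dataclass
class OrganismReference:
    """A genome reference: ordered chromosomes, optional bands, gene index."""

    id: str
    display_name: str
    build: str
    chromosomes: Sequence[Chromosome]
    species: str = ""
    cytobands: Sequence[CytobandEntry] = field(default_factory=tuple)
    gene_index: _GeneIndex = field(default_factory=_GeneIndex)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ReferenceSpecError(f"reference {self.id!r} has no chromosomes")
        seen: set[str] = set()
        dupes = [c.name for c in self.chromosomes if c.name in seen or seen.add(c.name)]
        if dupes:
            raise ReferenceSpecError(
                f"reference {self.id!r}: duplicate chromosome names {sorted(set(dupes))}"
            )
        lengths = self.chrom_lengths
        for band in self.cytobands:
            if band.locus.chrom not in lengths:
                raise ReferenceSpecError(
                    f"cytoband {band.band_name!r} on unknown chromosome {band.locus.chrom!r}"
                )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length_bp for c in self.chromosomes}

    @property
    def genome_length(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    def match_chromosome(self, name: str) -> str | None:
        """Resolve a chromosome name, tolerating a ``chr`` prefix mismatch."""
        lengths = self.chrom_lengths
        if name in lengths:
            return name
        low = name.lower()
        if low.startswith("chr") and name[3:] in lengths:
            return name[3:]
        if "chr" + name in lengths:
            return "chr" + name
        return None

    def lookup_gene(self, label: str) -> Locus | None:
        return self.gene_index.get(label)

    def with_gene_index(self, entries: Mapping[str, Locus]) -> "OrganismReference":
        """Return a copy of this reference carrying the given gene index."""
        idx = _GeneIndex()
        lengths = self.chrom_lengths
        for label, locus in entries.items():
            chrom = self.match_chromosome(locus.chrom)
            if chrom is None:
                raise ReferenceSpecError(
                    f"gene {label!r}: unknown chromosome {locus.chrom!r}"
                )
            if locus.end > lengths[chrom]:
                raise ReferenceSpecError(
                    f"gene {label!r}: locus {locus} exceeds chromosome length "
                    f"{lengths[chrom]}"
                )
            if chrom != locus.chrom:
                locus = Locus(chrom, locus.start, locus.end)
            idx.add(label, locus)
        return OrganismReference(
            id=self.id,
            display_name=self.display_name,
            build=self.build,
            chromosomes=self.chromosomes,
            species=self.species,
            cytobands=self.cytobands,
            gene_index=idx,
        )


@dataclass
class CompositeReference:
    """Several organism references joined on a single circle.

    Member chromosomes are renamed ``<prefix>.<chrom>`` and concatenated in
    member order; each member keeps a perimeter color used when the circle
    is drawn.  Node labels may carry an explicit ``<prefix>|<label>``
    namespace to force resolution against one member.
    """

    members: Sequence[tuple[str, OrganismReference, str]]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ReferenceSpecError("a composite reference needs at least 2 members")
        prefixes = [p for p, _, _ in self.members]
        if len(set(prefixes)) != len(prefixes):
            raise ReferenceSpecError(f"duplicate member prefixes in {prefixes}")

    @property
    def id(self) -> str:
        return "+".join(p for p, _, _ in self.members)

    @property
    def display_name(self) -> str:
        return " + ".join(r.display_name for _, r, _ in self.members)

    @property
    def chromosomes(self) -> list[Chromosome]:
        return [
            Chromosome(f"{prefix}.{c.name}", c.length_bp)
            for prefix, ref, _ in self.members
            for c in ref.chromosomes
        ]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length_bp for c in self.chromosomes}

    @property
    def genome_length(self) -> int:
        return sum(r.genome_length for _, r, _ in self.members)

    @property
    def cytobands(self) -> tuple[CytobandEntry, ...]:
        return ()  # stain coloring is replaced by member perimeter colors

    def member_color(self, chrom: str) -> str | None:
        prefix = chrom.split(".", 1)[0]
        for p, _, color in self.members:
            if p == prefix:
                return color
        return None

    def match_chromosome(self, name: str) -> str | None:
        lengths = self.chrom_lengths
        if name in lengths:
            return name
        for prefix, ref, _ in self.members:
            hit = ref.match_chromosome(name)
            if hit is not None:
                return f"{prefix}.{hit}"
        return None

    def lookup_gene(self, label: str) -> Locus | None:
        hits = self.lookup_gene_all(label)
        return hits[0][1] if hits else None

    def lookup_gene_all(self, label: str) -> list[tuple[str, Locus]]:
        """All (prefix, prefixed locus) gene-index hits, in member order."""
        out = []
        for prefix, ref, _ in self.members:
            locus = ref.lookup_gene(label)
            if locus is not None:
                out.append((prefix, Locus(f"{prefix}.{locus.chrom}", locus.start, locus.end)))
        return out


Reference = Union[OrganismReference, CompositeReference]


def parse_position_label(label: str) -> Locus:
    """Parse a positional node label of the form ``chr:start:end``.

    Raises :class:`PositionLabelError` on missing fields, non-integer
    coordinates, a start below 1, or an inverted span.
    """
    m = _POS_RE.match(label.strip())
    if not m:
        raise PositionLabelError(f"not a chr:start:end positional label: {label!r}")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    return Locus(chrom, start, end)  # Locus validates the span


def translate_label(label: str, ref: Reference) -> Locus | Unmapped:
    """Translate a node label to a locus against a reference.

    Resolution order: positional ``chr:start:end`` syntax, then exact gene
    index lookup (case-normalized for symbols).  On a composite reference a
    ``<prefix>|<label>`` form restricts the lookup to that member; an
    un-prefixed label tries members in order and the first hit wins.

    Never raises: anything unresolvable returns :class:`Unmapped` with a
    reason string.
    """
    label = label.strip()
    if not label:
        return Unmapped("empty label")

    if isinstance(ref, CompositeReference) and "|" in label:
        prefix, rest = label.split("|", 1)
        for p, member, _ in ref.members:
            if p == prefix:
                hit = translate_label(rest, member)
                if isinstance(hit, Unmapped):
                    return hit
                return Locus(f"{prefix}.{hit.chrom}", hit.start, hit.end)
        return Unmapped(f"unknown composite prefix {prefix!r}")

    if _POS_RE.match(label):
        try:
            locus = parse_position_label(label)
        except PositionLabelError as exc:
            return Unmapped(str(exc))
        chrom = ref.match_chromosome(locus.chrom)
        if chrom is None:
            return Unmapped("unknown chromosome")
        if locus.end > ref.chrom_lengths[chrom]:
            return Unmapped(
                f"position beyond chromosome end ({ref.chrom_lengths[chrom]} bp)"
            )
        return Locus(chrom, locus.start, locus.end)

    hit = ref.lookup_gene(label)
    if hit is not None:
        return hit
    return Unmapped("label not in gene index")


def define_custom_reference(
    name: str, chrom_table: Iterable[tuple[str, int]]
) -> OrganismReference:
    """Build a custom organism from (chromosome name, base length) rows."""
    rows = list(chrom_table)
    if not rows:
        raise ReferenceSpecError("custom reference needs at least one chromosome")
    bad = [
        (i + 1, n, l)
        for i, (n, l) in enumerate(rows)
        if not n or int(l) < 1 or [m for m, _ in rows].count(n) > 1
    ]
    if bad:
        detail = "; ".join(f"row {i}: ({n!r}, {l})" for i, n, l in bad)
        raise ReferenceSpecError(f"invalid custom chromosome rows: {detail}")
    return OrganismReference(
        id=name,
        display_name=name,
        build="custom",
        chromosomes=tuple(Chromosome(n, int(l)) for n, l in rows),
    )


def combine_references(
    members: Sequence[tuple[str, OrganismReference, str]]
) -> CompositeReference:
    """Join >= 2 references on one circle; see :class:`CompositeReference`."""
    return CompositeReference(members=tuple(members))


# ---------------------------------------------------------------------------
# file I/O: chromosome tables, cytobands, gene indices, bundled catalog

def read_chrom_table(lines: Iterable[str], source: str = "<stream>") -> list[tuple[str, int]]:
    """Read a ``chrom<TAB>length_bp`` table (comments ``#`` and blanks skipped)."""
    out: list[tuple[str, int]] = []
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ReferenceSpecError(f"{source}:{lineno}: expected 'chrom<TAB>length_bp'")
        try:
            out.append((parts[0], int(parts[1])))
        except ValueError:
            raise ReferenceSpecError(f"{source}:{lineno}: length {parts[1]!r} is not an integer") from None
    return out


def _read_cytobands(lines: Iterable[str], source: str) -> list[CytobandEntry]:
    out: list[CytobandEntry] = []
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ReferenceSpecError(
                f"{source}:{lineno}: expected 'chrom<TAB>start<TAB>end<TAB>band<TAB>stain'"
            )
        chrom, start, end, band, stain = parts
        out.append(CytobandEntry(Locus(chrom, int(start), int(end)), band, stain))
    return out


def load_gene_index(lines: Iterable[str], source: str = "<stream>") -> dict[str, Locus]:
    """Read a ``label<TAB>chrom<TAB>start<TAB>end`` gene index table.

    Multiple aliases may point at the same locus (one row per alias).
    """
    out: dict[str, Locus] = {}
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 4:
            raise ReferenceSpecError(
                f"{source}:{lineno}: expected 'label<TAB>chrom<TAB>start<TAB>end'"
            )
        label, chrom, start, end = parts
        out[label] = Locus(chrom, int(start), int(end))
    return out


def _data_text(filename: str) -> str:
    return resources.files("genarc.data").joinpath(filename).read_text(encoding="utf-8")


def load_catalog() -> list[OrganismReference]:
    """Load the ten bundled organism references from the static data tables.

    Built-in references ship without genome-scale gene tables: their gene
    indices are empty and pluggable via
    :meth:`OrganismReference.with_gene_index`.
    """
    refs: list[OrganismReference] = []
    try:
        catalog_text = _data_text("catalog.tsv")
    except OSError as exc:
        raise ReferenceSpecError(f"cannot read bundled catalog.tsv: {exc}") from exc
    for lineno, raw in enumerate(catalog_text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ReferenceSpecError(f"catalog.tsv:{lineno}: expected 6 tab-separated columns")
        org_id, display, species, build, chrom_file, cyto_file = parts
        try:
            chrom_rows = read_chrom_table(_data_text(chrom_file).splitlines(), chrom_file)
        except (OSError, ReferenceSpecError) as exc:
            raise ReferenceSpecError(f"corrupted bundled table {chrom_file}: {exc}") from exc
        cytobands: tuple[CytobandEntry, ...] = ()
        if cyto_file != "-":
            try:
                cytobands = tuple(_read_cytobands(_data_text(cyto_file).splitlines(), cyto_file))
            except (OSError, ReferenceSpecError) as exc:
                raise ReferenceSpecError(f"corrupted bundled table {cyto_file}: {exc}") from exc
        refs.append(
            OrganismReference(
                id=org_id,
                display_name=display,
                build=build,
                species=species,
                chromosomes=tuple(Chromosome(n, l) for n, l in chrom_rows),
                cytobands=cytobands,
            )
        )
    return refs


def get_reference(org_id: str) -> OrganismReference:
    """Fetch one built-in reference by catalog id (e.g. ``"yeast"``)."""
    for ref in load_catalog():
        if ref.id == org_id:
            return ref
    known = ", ".join(r.id for r in load_catalog())
    raise KeyError(f"unknown organism id {org_id!r}; built-ins: {known}")
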