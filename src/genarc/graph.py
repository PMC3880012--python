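"""Association sets: label resolution, filtering, render limit, bundling.

An :class:`AssociationSet` keeps every parsed edge in input order together
with a mapping report saying which node labels resolved to genomic loci.
Edges whose endpoints cannot all be placed are retained in the set (they
still appear in grid/network exports) but only these take part in circular
geometry:

* *drawable* edges — both endpoints mapped, drawn as inner arcs;
* *glyph* edges — exactly one endpoint mapped, the other a PHENO
  (phenotype, no genomic location) node, drawn as an outer tick at the
  mapped partner's position.

Filters (weight predicates and label-set membership) always operate on the
full set; the render limit (first N edges, default 2000) is a pure
view-layer truncation applied only when drawing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

from .assoc_io import EdgeRecord
from .reference import Locus, Reference, Unmapped, translate_label

__all__ = [
    "Node",
    "Association",
    "MappingReport",
    "AssociationSet",
    "FilterSpec",
    "BundleSpec",
    "Bundle",
    "NothingToPlotError",
    "WEIGHT_OPS",
    "DEFAULT_RENDER_LIMIT",
    "resolve_set",
    "filter_weight",
    "filter_labels",
    "apply_render_limit",
    "bundle",
]

DEFAULT_RENDER_LIMIT = 2000

WEIGHT_OPS: dict[str, Callable[[float, float], bool]] = {
    "<": lambda w, t: w < t,
    "<=": lambda w, t: w <= t,
    ">": lambda w, t: w > t,
    ">=": lambda w, t: w >= t,
    "==": lambda w, t: w == t,
    "abs>=": lambda w, t: abs(w) >= t,
    "abs<=": lambda w, t: abs(w) <= t,
}


class NothingToPlotError(ValueError):
    """No edge in the set can be placed on the circle."""


@dataclass(frozen=True)
class Node:
    """A labelled endpoint with its omics source type and resolved locus."""

    label: str
    source_type: str | None
    locus: Locus | Unmapped

    @property
    def mapped(self) -> bool:
        return isinstance(self.locus, Locus)

    @property
    def is_pheno(self) -> bool:
        return self.source_type == "PHENO"


@dataclass(frozen=True)
class Association:
    """An undirected edge between two nodes, optionally weighted/colored."""

    a: Node
    b: Node
    weight: float | None = None
    color: str | None = None
    relation: str | None = None

    @property
    def drawable(self) -> bool:
        return self.a.mapped and self.b.mapped

    @property
    def glyph(self) -> bool:
        """One endpoint mapped, the other an unmapped PHENO feature."""
        return (self.a.mapped and not self.b.mapped and self.b.is_pheno) or (
            self.b.mapped and not self.a.mapped and self.a.is_pheno
        )

    @property
    def is_self_edge(self) -> bool:
        return self.a.label == self.b.label

    def key(self) -> tuple:
        return (self.a.label, self.a.source_type, self.b.label,
                self.b.source_type, self.weight, self.color)


@dataclass(frozen=True)
class MappingReport:
    """Label resolution accounting: total = mapped + unmapped + pheno."""

    total: int
    mapped: int
    unmapped: int
    pheno: int
    unmapped_labels: tuple[tuple[str, str], ...] = ()  # (label, reason)
    self_edges: int = 0
    duplicate_edges: int = 0
    multi_member_labels: tuple[str, ...] = ()  # composite: label hit >1 member

    def summary(self) -> str:
        return (
            f"labels: {self.total} total, {self.mapped} mapped, "
            f"{self.unmapped} unmapped, {self.pheno} phenotype"
        )


@dataclass(frozen=True)
class AssociationSet:
    """Resolved edges in input order plus their mapping report."""

    edges: tuple[Association, ...]
    report: MappingReport
    reference: Reference | None = None
    provenance: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.edges)

    def drawable_edges(self) -> list[Association]:
        return [e for e in self.edges if e.drawable]

    def glyph_edges(self) -> list[Association]:
        return [e for e in self.edges if e.glyph]

    def edge_keys(self) -> Counter:
        return Counter(e.key() for e in self.edges)


@dataclass(frozen=True)
class FilterSpec:
    """Filter settings: optional weight predicate, optional label set."""

    weight_op: str | None = None
    weight_threshold: float | None = None
    label_set: frozenset[str] | None = None
    label_mode: str = "any"  # any-endpoint | both-endpoints
    render_limit: int = DEFAULT_RENDER_LIMIT


@dataclass(frozen=True)
class BundleSpec:
    """Edge-bundling settings: fixed window width, optional score opt-out."""

    window_bp: int
    exclude_abs_weight_ge: float | None = None

    def __post_init__(self) -> None:
        if self.window_bp < 1:
            raise ValueError("bundling window_bp must be >= 1")


@dataclass(frozen=True)
class Bundle:
    """Edges whose endpoint midpoints share the same pair of windows."""

    key: tuple[tuple[str, int], tuple[str, int]]  # sorted (chrom, window idx)
    members: tuple[Association, ...]

    @property
    def count(self) -> int:
        return len(self.members)


def _resolve_node(
    label: str,
    source_type: str | None,
    reference: Reference,
    cache: dict[str, Locus | Unmapped],
) -> Node:
    if source_type == "PHENO":
        # phenotype features never enter circular geometry, even when the
        # label happens to be resolvable
        return Node(label, source_type, Unmapped("phenotype feature (no genomic location)"))
    if label not in cache:
        cache[label] = translate_label(label, reference)
    return Node(label, source_type, cache[label])


def resolve_set(records: Iterable[EdgeRecord], reference: Reference) -> AssociationSet:
    """Resolve parsed edge records against a reference.

    Every record is kept, in input order.  Raises
    :class:`NothingToPlotError` when not a single edge can be placed on the
    circle, naming the most frequent unmapped labels.
    """
    from .reference import CompositeReference

    cache: dict[str, Locus | Unmapped] = {}
    edges: list[Association] = []
    pheno_labels: set[str] = set()
    seen_keys: Counter = Counter()
    for rec in records:
        a = _resolve_node(rec.label_a, rec.type_a, reference, cache)
        b = _resolve_node(rec.label_b, rec.type_b, reference, cache)
        for node in (a, b):
            if node.is_pheno:
                pheno_labels.add(node.label)
        edges.append(Association(a, b, rec.weight, rec.color, rec.relation))
        seen_keys[edges[-1].key()] += 1

    mapped_labels = {lbl for lbl, loc in cache.items() if isinstance(loc, Locus)}
    unmapped = tuple(
        (lbl, loc.reason)
        for lbl, loc in cache.items()
        if isinstance(loc, Unmapped) and lbl not in pheno_labels
    )
    multi = ()
    if isinstance(reference, CompositeReference):
        multi = tuple(
            lbl for lbl in mapped_labels
            if "|" not in lbl and len(reference.lookup_gene_all(lbl)) > 1
        )
    report = MappingReport(
        total=len(mapped_labels) + len(unmapped) + len(pheno_labels),
        mapped=len(mapped_labels),
        unmapped=len(unmapped),
        pheno=len(pheno_labels),
        unmapped_labels=unmapped,
        self_edges=sum(1 for e in edges if e.is_self_edge),
        duplicate_edges=sum(n - 1 for n in seen_keys.values() if n > 1),
        multi_member_labels=multi,
    )
    aset = AssociationSet(edges=tuple(edges), report=report, reference=reference)
    if edges and not any(e.drawable or e.glyph for e in edges):
        worst = Counter()
        for e in edges:
            for node in (e.a, e.b):
                if not node.mapped and not node.is_pheno:
                    worst[node.label] += 1
        top = ", ".join(lbl for lbl, _ in worst.most_common(5))
        raise NothingToPlotError(
            f"nothing to plot: no edge has mappable endpoints (top unmapped: {top})"
        )
    if not edges:
        raise NothingToPlotError("nothing to plot: empty association set")
    return aset


def _recount(aset: AssociationSet, edges: Sequence[Association],
             step: str) -> AssociationSet:
    """Rebuild the set around a filtered edge list, recomputing the report."""
    labels: dict[str, Node] = {}
    for e in edges:
        for node in (e.a, e.b):
            labels.setdefault(node.label, node)
    mapped = sum(1 for n in labels.values() if n.mapped)
    pheno = sum(1 for n in labels.values() if n.is_pheno)
    unmapped = tuple(
        (n.label, n.locus.reason)
        for n in labels.values()
        if not n.mapped and not n.is_pheno
    )
    keys = Counter(e.key() for e in edges)
    report = MappingReport(
        total=len(labels),
        mapped=mapped,
        unmapped=len(unmapped),
        pheno=pheno,
        unmapped_labels=unmapped,
        self_edges=sum(1 for e in edges if e.is_self_edge),
        duplicate_edges=sum(n - 1 for n in keys.values() if n > 1),
        multi_member_labels=aset.report.multi_member_labels,
    )
    return replace(aset, edges=tuple(edges), report=report,
                   provenance=aset.provenance + (step,))


def filter_weight(aset: AssociationSet, op: str, threshold: float) -> AssociationSet:
    """Keep edges whose weight satisfies ``op threshold``.

    Edges without a numeric weight are dropped: weight filtering applies
    only where numeric values were provided.
    """
    if op not in WEIGHT_OPS:
        raise ValueError(f"unknown weight operator {op!r}; known: {sorted(WEIGHT_OPS)}")
    pred = WEIGHT_OPS[op]
    kept = [e for e in aset.edges if e.weight is not None and pred(e.weight, threshold)]
    return _recount(aset, kept, f"weight {op} {threshold:g}")


def _norm(label: str) -> str:
    return label.strip().casefold()


def filter_labels(
    aset: AssociationSet, labels: Iterable[str], mode: str = "any"
) -> AssociationSet:
    """Keep edges touching a label set (e.g. a pathway's gene list).

    ``mode="any"`` keeps edges with at least one endpoint in the set,
    ``mode="both"`` requires both endpoints.  Matching is on trimmed,
    case-folded labels.
    """
    wanted = {_norm(l) for l in labels if l.strip()}
    if not wanted:
        raise ValueError("label filter requires a non-empty label set")
    if mode not in ("any", "both"):
        raise ValueError(f"label filter mode must be 'any' or 'both', got {mode!r}")
    combine = any if mode == "any" else all
    kept = [
        e for e in aset.edges
        if combine(_norm(n.label) in wanted for n in (e.a, e.b))
    ]
    return _recount(aset, kept, f"labels[{mode}] n={len(wanted)}")


def apply_render_limit(aset: AssociationSet, n: int = DEFAULT_RENDER_LIMIT) -> AssociationSet:
    """First ``n`` edges in current order — a view-layer truncation.

    Apply only after all filters: filtering always sees the full set.
    """
    if n < 1:
        raise ValueError("render limit must be >= 1")
    if n >= len(aset.edges):
        return aset
    return _recount(aset, aset.edges[:n], f"limit {n}")


def _window_key(locus: Locus, window_bp: int) -> tuple[str, int]:
    return (locus.chrom, (locus.midpoint - 1) // window_bp)


def bundle(
    aset: AssociationSet, spec: BundleSpec
) -> tuple[list[Bundle], list[Association]]:
    """Group drawable edges whose endpoints share genomic windows.

    Each chromosome is partitioned into consecutive fixed windows of
    ``window_bp`` starting at base 1; an edge's key is the unordered pair
    of (chromosome, window index) of its endpoint midpoints, so A→B and
    B→A bundle together.  Edges with ``|weight| >=
    exclude_abs_weight_ge`` (when set) bypass bundling and are returned
    separately for individual drawing.  Only drawable (mapped-mapped)
    edges participate.
    """
    groups: dict[tuple, list[Association]] = {}
    passthrough: list[Association] = []
    for e in aset.drawable_edges():
        if (
            spec.exclude_abs_weight_ge is not None
            and e.weight is not None
            and abs(e.weight) >= spec.exclude_abs_weight_ge
        ):
            passthrough.append(e)
            continue
        ka = _window_key(e.a.locus, spec.window_bp)
        kb = _window_key(e.b.locus, spec.window_bp)
        key = tuple(sorted((ka, kb)))
        groups.setdefault(key, []).append(e)
    bundles = [Bundle(key=k, members=tuple(v)) for k, v in groups.items()]
    return bundles, passthrough
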