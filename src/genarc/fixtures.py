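"""Seeded synthetic references, gene indices, association sets and rings.

Everything here is generated data for exercising the pipeline without any
downloads: a random genome with a gene index, weighted association files
in any supported dialect, and a complete "correlation study" scenario
(heatmap/bar rings, a pathway-like gene subset, weighted edges) shaped
like a copy-number / expression correlation analysis.

All generators are driven by ``numpy.random.default_rng(seed)``; the same
seed always yields byte-identical files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assoc_io import AnnotationRingSpec, parse_annotation_ring
from .reference import Locus, OrganismReference, define_custom_reference

__all__ = [
    "FixtureSpec",
    "Scenario",
    "make_reference",
    "make_associations",
    "make_ring",
    "make_scenario_fig2like",
    "write_scenario",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for synthetic data generation.

    Weights emulate correlation-style edge scores and are drawn
    uniform[-1, 1]; ``pheno_fraction`` is the per-edge probability that the
    second endpoint is replaced by an unmapped phenotype feature.
    """

    seed: int = 0
    n_chrom: int = 5
    chrom_length_range: tuple[int, int] = (1_000_000, 5_000_000)
    n_genes: int = 200
    n_edges: int = 500
    weight_fraction: float = 1.0
    color_fraction: float = 0.0
    pheno_fraction: float = 0.0
    positional_fraction: float = 0.1
    gene_span_range: tuple[int, int] = (500, 20_000)
    dialect: str = "tsv"


_DELIMS = {"txt": " ", "tsv": "\t", "csv": ","}


def make_reference(spec: FixtureSpec) -> OrganismReference:
    """A random genome with an attached three-alias gene index.

    Every gene is indexed under a symbol (``G0001``), an ENSEMBL-like id
    (``ENSFIX00000000001``) and an ENTREZ-like numeric id, all pointing at
    the same locus, so that every label grammar branch gets exercised.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.chrom_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_chrom)
    ref = define_custom_reference(
        f"fixture-{spec.seed}",
        [(f"chr{i + 1}", int(L)) for i, L in enumerate(lengths)],
    )
    max_span = max(spec.gene_span_range)
    if spec.n_genes > 0 and any(L <= max_span + 1 for L in lengths):
        raise ValueError(
            "infeasible fixture spec: chromosomes shorter than the maximum "
            "gene span; enlarge chrom_length_range or shrink gene_span_range"
        )
    index: dict[str, Locus] = {}
    for i in range(spec.n_genes):
        ci = int(rng.integers(0, spec.n_chrom))
        span = int(rng.integers(spec.gene_span_range[0], spec.gene_span_range[1] + 1))
        start = int(rng.integers(1, int(lengths[ci]) - span + 1))
        locus = Locus(f"chr{ci + 1}", start, start + span - 1)
        index[f"G{i + 1:04d}"] = locus
        index[f"ENSFIX{i + 1:011d}"] = locus
        index[str(100_000 + i)] = locus
    return ref.with_gene_index(index)


def gene_symbols(spec: FixtureSpec) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(spec.n_genes)]


def _alias(i: int, form: int) -> str:
    return (f"G{i + 1:04d}", f"ENSFIX{i + 1:011d}", str(100_000 + i))[form]


def make_associations(spec: FixtureSpec, reference: OrganismReference) -> str:
    """Association file text in the spec's dialect.

    Endpoints are drawn from the gene index (random alias form) with a
    slice of positional ``chr:start:end`` labels; weights, explicit
    colors, and phenotype endpoints appear at the configured rates.
    """
    if spec.n_genes == 0 and spec.positional_fraction == 0:
        raise ValueError("cannot draw edges: no genes and no positional labels")
    rng = np.random.default_rng(spec.seed + 1)
    lengths = {c.name: c.length_bp for c in reference.chromosomes}
    chrom_names = list(lengths)

    def endpoint() -> str:
        if spec.n_genes == 0 or rng.random() < spec.positional_fraction:
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            span = int(rng.integers(1, 50_000))
            start = int(rng.integers(1, max(2, lengths[chrom] - span)))
            return f"{chrom}:{start}:{start + span - 1}"
        i = int(rng.integers(0, spec.n_genes))
        return _alias(i, int(rng.integers(0, 3)))

    lines: list[str] = [f"# synthetic associations (seed {spec.seed})"]
    for k in range(spec.n_edges):
        a = endpoint()
        b = endpoint()
        if rng.random() < spec.pheno_fraction:
            b = f"PHENO{k:05d}^PHENO"
        extra = None
        if rng.random() < spec.weight_fraction:
            extra = repr(round(float(rng.uniform(-1.0, 1.0)), 6))
        elif rng.random() < spec.color_fraction:
            extra = "#{:02x}{:02x}{:02x}".format(*rng.integers(0, 256, size=3))
        if spec.dialect == "sif":
            fields = [a, "assoc", b] + ([extra] if extra else [])
            lines.append(" ".join(fields))
        else:
            delim = _DELIMS[spec.dialect]
            fields = [a, b] + ([extra] if extra else [])
            lines.append(delim.join(fields))
    return "\n".join(lines) + "\n"


def make_ring(
    style: str,
    targets: list[str],
    seed: int,
    colors: bool = False,
    name: str = "ring",
) -> tuple[str, AnnotationRingSpec]:
    """An annotation ring file (text) plus its parsed spec."""
    rng = np.random.default_rng(seed)
    lines = [f"#ring {style}"]
    for t in targets:
        if colors:
            payload = "#{:02x}{:02x}{:02x}".format(*rng.integers(0, 256, size=3))
        else:
            payload = repr(round(float(rng.uniform(-1.0, 1.0)), 4))
        lines.append(f"{t}\t{payload}")
    text = "\n".join(lines) + "\n"
    spec = parse_annotation_ring(io.StringIO(text), source=name)
    return text, spec


@dataclass
class Scenario:
    """A self-contained end-to-end input bundle."""

    reference: OrganismReference
    associations_text: str
    associations_filename: str
    ring_texts: list[str] = field(default_factory=list)
    ring_specs: list[AnnotationRingSpec] = field(default_factory=list)
    gene_subset: list[str] = field(default_factory=list)
    spec: FixtureSpec | None = None


def make_scenario_fig2like(seed: int, n_edges: int = 5000) -> Scenario:
    """A correlation-study scenario: weighted edges, 4 rings, a gene subset.

    Emulates the structure of a copy-number / expression correlation
    analysis: two heatmap rings of segment-level values (gain/loss-like),
    two bar rings of per-gene values, correlation-like edge weights in
    [-1, 1], and a 40-gene pathway-like subset usable for label filtering.
    All values are synthetic.
    """
    spec = FixtureSpec(
        seed=seed,
        n_chrom=8,
        chrom_length_range=(20_000_000, 80_000_000),
        n_genes=400,
        n_edges=n_edges,
        weight_fraction=1.0,
        positional_fraction=0.0,
        dialect="tsv",
    )
    reference = make_reference(spec)
    associations = make_associations(spec, reference)
    rng = np.random.default_rng(seed + 2)
    symbols = gene_symbols(spec)
    subset = sorted(
        symbols[i] for i in rng.choice(len(symbols), size=40, replace=False)
    )
    lengths = {c.name: c.length_bp for c in reference.chromosomes}
    segments = []
    for chrom, L in lengths.items():
        n_seg = 6
        bounds = np.linspace(1, L, n_seg + 1, dtype=int)
        segments += [
            f"{chrom}:{int(bounds[i]) + (1 if i else 0)}:{int(bounds[i + 1])}"
            for i in range(n_seg)
        ]
    gene_targets = [symbols[i] for i in rng.choice(len(symbols), size=120, replace=False)]
    rings = [
        make_ring("heatmap", segments, seed + 3, name="cnv-like-A"),
        make_ring("bar", gene_targets[:60], seed + 4, name="expr-like-A"),
        make_ring("heatmap", segments, seed + 5, name="cnv-like-B"),
        make_ring("bar", gene_targets[60:], seed + 6, name="expr-like-B"),
    ]
    return Scenario(
        reference=reference,
        associations_text=associations,
        associations_filename="associations.tsv",
        ring_texts=[t for t, _ in rings],
        ring_specs=[s for _, s in rings],
        gene_subset=subset,
        spec=spec,
    )


def write_scenario(scenario: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Write a scenario to disk as plain-text pipeline inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    chrom_path = out / "reference.tsv"
    chrom_path.write_text(
        "".join(f"{c.name}\t{c.length_bp}\n" for c in scenario.reference.chromosomes),
        encoding="utf-8",
    )
    paths["reference"] = chrom_path

    index_path = out / "gene_index.tsv"
    index_path.write_text(
        "".join(
            f"{label}\t{locus.chrom}\t{locus.start}\t{locus.end}\n"
            for label, locus in scenario.reference.gene_index.items()
        ),
        encoding="utf-8",
    )
    paths["gene_index"] = index_path

    assoc_path = out / scenario.associations_filename
    assoc_path.write_text(scenario.associations_text, encoding="utf-8")
    paths["associations"] = assoc_path

    for i, text in enumerate(scenario.ring_texts):
        ring_path = out / f"ring_{i}.txt"
        ring_path.write_text(text, encoding="utf-8")
        paths[f"ring_{i}"] = ring_path

    subset_path = out / "gene_subset.txt"
    subset_path.write_text("\n".join(scenario.gene_subset) + "\n", encoding="utf-8")
    paths["gene_subset"] = subset_path
    return paths
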