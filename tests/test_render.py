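"""SVG contracts: well-formedness, element counts, colors, determinism."""

import io

import pytest
from lxml import etree  # independent XML well-formedness oracle

from genarc import (
    BundleSpec,
    LayoutConfig,
    bundle,
    build_arcmap,
    export_svg,
    filter_weight,
    get_reference,
    render_annotation_ring,
    render_circular,
    render_grid,
    render_grid_html,
    resolve_set,
)
from genarc.assoc_io import DIALECTS, EdgeRecord, parse_annotation_ring, parse_associations
from genarc.fixtures import make_scenario_fig2like
from genarc.render import weight_color

from conftest import resolve_text


def build(ref, aset, rings=(), **kw):
    cfg = LayoutConfig()
    arcmap = build_arcmap(ref, cfg)
    return render_circular(aset, arcmap, cfg, ref, rings=rings, **kw)


def xml_ok(doc):
    etree.fromstring(doc.tostring())  # raises on malformed XML
    return True


class TestCircularContracts:
    def test_bands_equal_chromosomes_and_wellformed(self, small_ref, small_set):
        doc = build(small_ref, small_set)
        assert xml_ok(doc)
        assert doc.root.tag == "svg"
        assert doc.count_class("chrom-band") == len(small_ref.chromosomes)
        assert doc.count_class("edge") == len(small_set.drawable_edges())

    def test_render_limit_caps_edge_curves(self, small_ref):
        text = "".join(f"G7\tAbcA\t0.{i}\n" for i in range(1, 6))
        aset = resolve_text(text, small_ref)
        doc = build(small_ref, aset, render_limit=2)
        assert doc.count_class("edge") == 2

    def test_glyph_ticks_equal_single_pheno_edges(self, small_ref):
        aset = resolve_set(
            [
                EdgeRecord("G7", "AbcA", weight=0.1),
                EdgeRecord("G7", "t1", None, "PHENO"),
                EdgeRecord("Zeta", "t2", None, "PHENO"),
            ],
            small_ref,
        )
        doc = build(small_ref, aset)
        assert doc.count_class("glyph") == 2

    def test_filtered_to_empty_set_renders_reference_ring_only(self, small_ref, small_set):
        empty = filter_weight(small_set, ">=", 99.0)
        doc = build(small_ref, empty)
        assert doc.count_class("edge") == 0
        assert doc.count_class("chrom-band") == len(small_ref.chromosomes)

    def test_explicit_color_beats_weight_colormap(self, small_ref):
        aset = resolve_text("G7\tAbcA\t#123456\nAbcA\tZeta\t0.9\n", small_ref)
        doc = build(small_ref, aset)
        strokes = [e.get("stroke") for e in doc.elements_of_class("edge")]
        assert "#123456" in strokes

    def test_positive_green_negative_pink_weight_colors(self):
        pos = weight_color(0.9, 1.0)
        neg = weight_color(-0.9, 1.0)
        zero = weight_color(0.0, 1.0)

        def rgb(h):
            return tuple(int(h[i:i + 2], 16) for i in (1, 3, 5))

        rp, gp, bp = rgb(pos)
        rn, gn, bn = rgb(neg)
        rz, gz, bz = rgb(zero)
        assert gp > rp and gp > bp          # positive: green side
        assert rn > gn                      # negative: pink side
        assert abs(rz - gz) < 12 and abs(gz - bz) < 12  # zero: neutral grey

    def test_cytoband_stains_drawn_for_human(self):
        human = get_reference("human")
        aset = resolve_set([EdgeRecord("1:100:200", "2:500:600", weight=0.5)], human)
        doc = build(human, aset)
        assert doc.count_class("cytoband") == len(human.cytobands)
        fills = {e.get("fill") for e in doc.elements_of_class("cytoband")}
        assert "#cc3333" in fills  # acen centromere bands

    def test_bundles_drawn_with_log_scaled_width(self, small_ref):
        aset = resolve_text(
            "chr1:100:110\tchr2:200:210\t0.1\n"
            "chr1:150:160\tchr2:240:250\t0.2\n"
            "chr1:120:130\tchr2:220:230\t0.3\n",
            small_ref,
        )
        bundled = bundle(aset, BundleSpec(window_bp=1000))
        doc = build(small_ref, aset, bundles=bundled)
        (el,) = doc.elements_of_class("bundle")
        assert el.get("data-count") == "3"
        assert float(el.get("stroke-width")) == pytest.approx(2.0)  # log2(4)

    def test_metadata_contains_filter_provenance(self, small_ref, small_set):
        filtered = filter_weight(small_set, "abs>=", 0.92)
        doc = build(small_ref, filtered)
        meta = doc.root.find("metadata")
        assert "abs>= 0.92" in meta.text

    def test_rerender_is_byte_identical(self, small_ref, small_set):
        a = build(small_ref, small_set).tostring()
        b = build(small_ref, small_set).tostring()
        assert a == b


class TestAnnotationRingRendering:
    def make_band(self):
        cfg = LayoutConfig()
        return cfg, (cfg.radius_outer - 40, cfg.radius_outer - 22)

    def test_heatmap_cell_covers_full_chromosome(self, small_ref):
        cfg, band = self.make_band()
        arcmap = build_arcmap(small_ref, cfg)
        ring = parse_annotation_ring(io.StringIO("#ring heatmap\nchr1:1:10000\t0.8\n"))
        els, skipped = render_annotation_ring(ring, band, arcmap, small_ref, cfg)
        cells = [e for e in els if e.get("class") == "ring-cell"]
        assert len(cells) == 1 and not skipped

    def test_histogram_symmetry(self, small_ref):
        cfg, band = self.make_band()
        arcmap = build_arcmap(small_ref, cfg)
        ring = parse_annotation_ring(
            io.StringIO("#ring histogram\nG7\t1\nAbcA\t-1\n")
        )
        els, _ = render_annotation_ring(ring, band, arcmap, small_ref, cfg)
        hist = [e for e in els if e.get("class") == "ring-hist"]
        assert len(hist) == 2

        def extent(el):
            dx = float(el.get("x2")) - float(el.get("x1"))
            dy = float(el.get("y2")) - float(el.get("y1"))
            return (dx * dx + dy * dy) ** 0.5

        # equal radial extents up to the 3-decimal coordinate precision
        assert extent(hist[0]) == pytest.approx(extent(hist[1]), abs=5e-3)

    def test_bar_ring_count_and_max_touches_band_edge(self, small_ref):
        import numpy as np

        cfg, band = self.make_band()
        arcmap = build_arcmap(small_ref, cfg)
        rng = np.random.default_rng(3)
        genes = ["G7", "AbcA", "Zeta"] * 4  # 12 entries? keep 10
        lines = ["#ring bar"] + [
            f"{g}\t{rng.uniform(-1, 1):.4f}" for g in genes[:10]
        ]
        ring = parse_annotation_ring(io.StringIO("\n".join(lines)))
        els, _ = render_annotation_ring(ring, band, arcmap, small_ref, cfg)
        bars = [e for e in els if e.get("class") == "ring-bar"]
        assert len(bars) == 10

        thickness = band[1] - band[0]

        def extent(el):
            dx = float(el.get("x2")) - float(el.get("x1"))
            dy = float(el.get("y2")) - float(el.get("y1"))
            return (dx * dx + dy * dy) ** 0.5

        assert max(extent(b) for b in bars) == pytest.approx(thickness, rel=1e-3)

    def test_unresolvable_targets_skipped_and_reported(self, small_ref):
        cfg, band = self.make_band()
        arcmap = build_arcmap(small_ref, cfg)
        ring = parse_annotation_ring(io.StringIO("#ring bar\nG7\t1\nNOPE\t2\n"))
        els, skipped = render_annotation_ring(ring, band, arcmap, small_ref, cfg)
        assert skipped == ["NOPE"]
        assert len([e for e in els if e.get("class") == "ring-bar"]) == 1

    def test_fully_unresolvable_ring_dropped_from_document(self, small_ref, small_set):
        ring = parse_annotation_ring(io.StringIO("#ring bar\nNOPE1\t1\nNOPE2\t2\n"))
        doc = build(small_ref, small_set, rings=[ring])
        assert doc.count_class("ring") == 0

    def test_fig2like_scenario_rings_resolve_and_render(self):
        scenario = make_scenario_fig2like(seed=2, n_edges=300)
        records = parse_associations(
            io.StringIO(scenario.associations_text), DIALECTS[".tsv"]
        )
        aset = resolve_set(records, scenario.reference)
        doc = build(scenario.reference, aset, rings=scenario.ring_specs)
        assert xml_ok(doc)
        assert doc.count_class("ring") == 4
        # rings appear in upload order
        classes = [
            el.get("class") for el in doc.root.iter()
            if "ring-" in (el.get("class") or "") and el.tag == "g"
        ]
        assert classes == [f"ring ring-{i}" for i in range(4)]


class TestGridAndExport:
    def test_grid_rows_and_order(self, small_set):
        text = render_grid(small_set)
        lines = text.strip().split("\n")
        assert len(lines) == 1 + len(small_set.edges)
        assert lines[0].split("\t")[0] == "label_a"
        assert lines[1].split("\t")[0] == "G7"

    def test_grid_marks_unmapped(self, small_ref):
        aset = resolve_text("G7\tBOGUS\nG7\tAbcA\n", small_ref)
        text = render_grid(aset)
        assert "unmapped" in text

    def test_grid_labels_weights_reparse_to_same_edges(self, small_set):
        text = render_grid(small_set)
        rows = [l.split("\t") for l in text.strip().split("\n")[1:]]
        reparsed = [(r[0], r[3], float(r[6]) if r[6] else None) for r in rows]
        assert reparsed == [
            (e.a.label, e.b.label, e.weight) for e in small_set.edges
        ]

    def test_grid_html_is_parseable(self, small_set):
        html = render_grid_html(small_set)
        etree.fromstring(html.split("\n", 1)[1].encode())  # skip doctype

    def test_export_svg_roundtrips_through_xml_parser(self, tmp_path, small_ref, small_set):
        doc = build(small_ref, small_set)
        out = tmp_path / "plot.svg"
        export_svg(doc, str(out))
        tree = etree.parse(str(out))
        root = tree.getroot()
        assert root.tag == "{http://www.w3.org/2000/svg}svg"
        assert root.get("width") and root.get("height")

    def test_export_is_deterministic_bytes(self, tmp_path, small_ref, small_set):
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        export_svg(build(small_ref, small_set), str(p1))
        export_svg(build(small_ref, small_set), str(p2))
        assert p1.read_bytes() == p2.read_bytes()
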