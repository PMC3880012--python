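"""Resolution, filtering, render limit, and bundling against brute-force oracles."""

import io

import numpy as np
import pytest

from genarc import (
    BundleSpec,
    NothingToPlotError,
    apply_render_limit,
    bundle,
    filter_labels,
    filter_weight,
    parse_associations,
    resolve_set,
)
from genarc.assoc_io import DIALECTS
from genarc.fixtures import FixtureSpec, make_associations, make_reference

from conftest import resolve_text


class TestResolveSet:
    def test_all_mapped(self, small_set):
        rep = small_set.report
        # distinct labels: G7, AbcA, Zeta, chr1:100:200
        assert (rep.total, rep.mapped, rep.unmapped, rep.pheno) == (4, 4, 0, 0)
        assert rep.mapped + rep.unmapped + rep.pheno == rep.total

    def test_edge_order_preserved(self, small_set):
        assert [e.a.label for e in small_set.edges] == ["G7", "AbcA", "Zeta"]

    def test_pheno_endpoint_kept_and_counted(self, small_ref):
        aset = resolve_text("G7\tobesity^PHENO\t0.4\n", small_ref)
        assert aset.report.pheno == 1
        assert len(aset.edges) == 1
        (edge,) = aset.edges
        assert edge.glyph and not edge.drawable

    def test_pheno_never_enters_geometry_even_if_label_resolvable(self, small_ref):
        aset = resolve_text("G7\tAbcA^PHENO\n", small_ref)
        (edge,) = aset.edges
        assert not edge.b.mapped and edge.glyph

    def test_unmapped_nonpheno_edge_retained_but_not_drawable(self, small_ref):
        aset = resolve_text("G7\tAbcA\nG7\tBOGUS\n", small_ref)
        assert len(aset.edges) == 2
        assert len(aset.drawable_edges()) == 1
        assert ("BOGUS", "label not in gene index") in aset.report.unmapped_labels

    def test_all_bogus_is_a_hard_error_naming_labels(self, small_ref):
        with pytest.raises(NothingToPlotError, match="BOGUS1"):
            resolve_text("BOGUS1\tBOGUS2\nBOGUS1\tBOGUS3\n", small_ref)

    def test_empty_set_is_a_hard_error(self, small_ref):
        with pytest.raises(NothingToPlotError):
            resolve_set([], small_ref)

    def test_self_and_duplicate_edges_flagged(self, small_ref):
        aset = resolve_text("G7\tG7\nG7\tAbcA\nG7\tAbcA\n", small_ref)
        assert aset.report.self_edges == 1
        assert aset.report.duplicate_edges == 1


def _random_set(seed, n_edges=200, pheno=0.0):
    spec = FixtureSpec(seed=seed, n_chrom=4, n_genes=60, n_edges=n_edges,
                       weight_fraction=0.9, pheno_fraction=pheno)
    ref = make_reference(spec)
    text = make_associations(spec, ref)
    records = parse_associations(io.StringIO(text), DIALECTS[".tsv"])
    return resolve_set(records, ref)


class TestWeightFilter:
    def test_abs_ge_enumeration(self, small_set):
        out = filter_weight(small_set, "abs>=", 0.92)
        assert len(out) == 2
        assert sorted(e.weight for e in out.edges) == [-0.95, 0.93]

    def test_tiny_threshold_is_identity_on_weighted(self, small_set):
        out = filter_weight(small_set, ">=", -1e18)
        assert [e.key() for e in out.edges] == [
            e.key() for e in small_set.edges if e.weight is not None
        ]

    def test_weightless_edges_dropped(self, small_ref):
        aset = resolve_text("G7\tAbcA\nAbcA\tZeta\t0.2\n", small_ref)
        out = filter_weight(aset, ">=", -10.0)
        assert len(out) == 1

    def test_unknown_operator_rejected(self, small_set):
        with pytest.raises(ValueError):
            filter_weight(small_set, "!=", 0.0)

    @pytest.mark.parametrize("op", ["<", "<=", ">", ">=", "==", "abs>=", "abs<="])
    def test_matches_bruteforce_predicate_scan(self, op):
        import operator as opmod

        # independent oracle: explicit per-edge predicate loop
        oracle_ops = {
            "<": opmod.lt, "<=": opmod.le, ">": opmod.gt, ">=": opmod.ge,
            "==": opmod.eq,
            "abs>=": lambda w, t: abs(w) >= t,
            "abs<=": lambda w, t: abs(w) <= t,
        }
        aset = _random_set(seed=3)
        for threshold in (-0.5, 0.0, 0.3, 0.92):
            expected = [
                e.key() for e in aset.edges
                if e.weight is not None and oracle_ops[op](e.weight, threshold)
            ]
            got = [e.key() for e in filter_weight(aset, op, threshold).edges]
            assert got == expected


class TestLabelFilter:
    @pytest.fixture
    def abc_set(self, small_ref):
        return resolve_text(
            "G7\tAbcA\nAbcA\tZeta\nZeta\tchr1:1:10\n", small_ref
        )

    def test_any_endpoint(self, abc_set):
        out = filter_labels(abc_set, {"G7"}, "any")
        assert [(e.a.label, e.b.label) for e in out.edges] == [("G7", "AbcA")]

    def test_both_endpoints(self, abc_set):
        out = filter_labels(abc_set, {"AbcA", "Zeta"}, "both")
        assert [(e.a.label, e.b.label) for e in out.edges] == [("AbcA", "Zeta")]

    def test_case_insensitive_matching(self, abc_set):
        out = filter_labels(abc_set, {"abca"}, "any")
        assert len(out) == 2

    def test_empty_label_set_rejected(self, abc_set):
        with pytest.raises(ValueError):
            filter_labels(abc_set, [], "any")

    @pytest.mark.parametrize("mode", ["any", "both"])
    def test_matches_bruteforce_membership_scan(self, mode):
        aset = _random_set(seed=5)
        rng = np.random.default_rng(11)
        labels = {e.a.label for e in aset.edges if rng.random() < 0.2}
        labels |= {"G0001", "G0002"}
        norm = {l.casefold() for l in labels}
        combine = any if mode == "any" else all
        expected = [
            e.key() for e in aset.edges
            if combine(n.label.casefold() in norm for n in (e.a, e.b))
        ]
        got = [e.key() for e in filter_labels(aset, labels, mode).edges]
        assert got == expected


class TestFilterAlgebra:
    def test_weight_and_label_filters_commute(self):
        aset = _random_set(seed=7)
        labels = {"G0001", "G0005", "G0010", "G0020"}
        a = filter_labels(filter_weight(aset, "abs>=", 0.3), labels, "any")
        b = filter_weight(filter_labels(aset, labels, "any"), "abs>=", 0.3)
        assert [e.key() for e in a.edges] == [e.key() for e in b.edges]

    def test_filters_are_idempotent(self):
        aset = _random_set(seed=9)
        once = filter_weight(aset, ">=", 0.1)
        twice = filter_weight(once, ">=", 0.1)
        assert [e.key() for e in once.edges] == [e.key() for e in twice.edges]


class TestRenderLimit:
    def test_first_n_by_input_order(self, small_set):
        out = apply_render_limit(small_set, 2)
        assert [e.key() for e in out.edges] == [e.key() for e in small_set.edges[:2]]

    def test_limit_at_least_size_is_identity(self, small_set):
        assert apply_render_limit(small_set, 99) is small_set

    def test_filter_then_limit_differs_from_limit_then_filter(self, small_ref):
        # crafted set: the high-weight edges sit at the end, so truncating
        # first would starve the filter
        lines = [f"G7\tAbcA\t0.{i}\n" for i in range(1, 6)]
        lines += [f"AbcA\tZeta\t0.9{i}\n" for i in range(5)]
        aset = resolve_text("".join(lines), small_ref)

        # oracle: both orders computed explicitly
        filter_first = [
            e.key() for e in aset.edges if e.weight is not None and e.weight >= 0.9
        ][:3]
        limit_first = [
            e.key() for e in aset.edges[:3]
            if e.weight is not None and e.weight >= 0.9
        ]
        assert filter_first != limit_first

        got = apply_render_limit(filter_weight(aset, ">=", 0.9), 3)
        assert [e.key() for e in got.edges] == filter_first


class TestBundling:
    def test_shared_windows_merge(self, small_ref):
        aset = resolve_text(
            "chr1:100:110\tchr2:200:210\nchr1:150:160\tchr2:240:250\n", small_ref
        )
        bundles, passthrough = bundle(aset, BundleSpec(window_bp=1000))
        assert len(bundles) == 1 and bundles[0].count == 2 and not passthrough

    def test_direction_ignored(self, small_ref):
        aset = resolve_text(
            "chr1:100:110\tchr2:200:210\nchr2:240:250\tchr1:150:160\n", small_ref
        )
        bundles, _ = bundle(aset, BundleSpec(window_bp=1000))
        assert len(bundles) == 1

    def test_window_one_merges_only_identical_midpoints(self, small_ref):
        aset = resolve_text(
            "chr1:100:110\tchr2:200:210\n"
            "chr1:100:110\tchr2:200:210\n"
            "chr1:101:111\tchr2:200:210\n",
            small_ref,
        )
        bundles, _ = bundle(aset, BundleSpec(window_bp=1))
        counts = sorted(b.count for b in bundles)
        assert counts == [1, 2]

    def test_score_exclusion_passthrough(self, small_ref):
        aset = resolve_text(
            "chr1:100:110\tchr2:200:210\t0.99\nchr1:150:160\tchr2:240:250\t0.10\n",
            small_ref,
        )
        bundles, passthrough = bundle(aset, BundleSpec(1000, exclude_abs_weight_ge=0.9))
        assert len(passthrough) == 1 and passthrough[0].weight == 0.99
        assert sum(b.count for b in bundles) == 1

    def test_matches_bruteforce_grouping_and_conserves_counts(self):
        aset = _random_set(seed=13, n_edges=500)
        spec = BundleSpec(window_bp=250_000, exclude_abs_weight_ge=0.8)
        bundles, passthrough = bundle(aset, spec)

        # oracle: independent regrouping by recomputed keys
        expected: dict[tuple, int] = {}
        n_pass = 0
        for e in aset.drawable_edges():
            if e.weight is not None and abs(e.weight) >= 0.8:
                n_pass += 1
                continue
            keys = []
            for node in (e.a, e.b):
                mid = (node.locus.start + node.locus.end) // 2
                keys.append((node.locus.chrom, (mid - 1) // spec.window_bp))
            key = tuple(sorted(keys))
            expected[key] = expected.get(key, 0) + 1

        got = {b.key: b.count for b in bundles}
        assert got == expected
        assert len(passthrough) == n_pass
        assert sum(b.count for b in bundles) + len(passthrough) == len(
            aset.drawable_edges()
        )
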