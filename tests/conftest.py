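import io

import pytest

from genarc import (
    Locus,
    define_custom_reference,
    detect_dialect,
    parse_associations,
    resolve_set,
)

TAB = detect_dialect("x.tsv")


@pytest.fixture
def small_ref():
    """Two-chromosome genome with a tiny three-grammar gene index."""
    ref = define_custom_reference("toy", [("chr1", 10_000), ("chr2", 30_000)])
    return ref.with_gene_index({
        "G7": Locus("chr1", 500, 900),
        "ENSTOY00000000007": Locus("chr1", 500, 900),
        "100007": Locus("chr1", 500, 900),
        "AbcA": Locus("chr2", 1_000, 2_000),
        "Zeta": Locus("chr2", 20_000, 25_000),
    })


def resolve_text(text, ref):
    records = parse_associations(io.StringIO(text), TAB)
    return resolve_set(records, ref)


@pytest.fixture
def small_set(small_ref):
    return resolve_text(
        "G7\tAbcA\t0.5\n"
        "AbcA\tZeta\t-0.95\n"
        "Zeta\tchr1:100:200\t0.93\n",
        small_ref,
    )
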