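import pytest

from mitonux.annotation_io import AnnotationTable, GeneRecord, GeneSet


def make_table(arms, x_arms=("X",), **flag_lists):
    """Build a table from a list of arm labels; flags by gene index lists."""
    testis = set(flag_lists.get("testis", ()))
    dup = set(flag_lists.get("dup", ()))
    records = [
        GeneRecord(f"g{i}", arm, testis_biased=i in testis, duplicate=i in dup)
        for i, arm in enumerate(arms)
    ]
    return AnnotationTable(records, x_arms=x_arms)


@pytest.fixture
def four_gene_table():
    """x1(X), a1(2L), x2(X), a2(3R) — the smallest balanced location example."""
    return AnnotationTable(
        [
            GeneRecord("x1", "X"),
            GeneRecord("a1", "2L"),
            GeneRecord("x2", "X"),
            GeneRecord("a2", "3R"),
        ]
    )


@pytest.fixture
def gene_set():
    def _make(name, ids):
        return GeneSet(name=name, gene_ids=frozenset(ids))

    return _make
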