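import numpy as np
import pytest

from dtilink import EmbeddingTable, KnowledgeGraph, Triple


@pytest.fixture
def five_line_triple_file(tmp_path):
    """5 triples over 4 entities and 2 relations, counted by hand."""
    path = tmp_path / "triples.tsv"
    path.write_text(
        "# comment line\n"
        "d1\tbinds\tp1\n"
        "d1\tbinds\tp2\n"
        "d2\tbinds\tp1\n"
        "d2\tsimilar_to\td1\n"
        "p1\tsimilar_to\tp2\n"
    )
    return path


@pytest.fixture
def toy_kg():
    return KnowledgeGraph.from_triples(
        [
            Triple("a", "r", "b"),
            Triple("a", "r", "c"),
            Triple("b", "r", "c"),
            Triple("c", "s", "a"),
        ]
    )


@pytest.fixture
def random_table():
    rng = np.random.default_rng(42)
    return EmbeddingTable([f"e{i}" for i in range(6)], rng.standard_normal((6, 8)))
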