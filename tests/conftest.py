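import pandas as pd
import pytest

import mirvote as mv

ALIAS_TSV = """\
#versions: v6 v7 v8 v9 v10 v11 v17
accession\tname\tversion_from\tversion_to\tstatus
MIMAT0000080\thsa-miR-189\tv6\tv9\tactive
MIMAT0000080\thsa-miR-24-1*\tv10\t-\tactive
MIMAT0000685\thsa-miR-34b\tv6\tv10\tactive
MIMAT0000685\thsa-miR-34b*\tv11\t-\tactive
MIMAT0004676\thsa-miR-34b\tv11\t-\tactive
MIMAT0001001\thsa-miR-stable\tv6\t-\tactive
MIMAT0002002\thsa-miR-gone\tv6\tv10\tretired
MIMAT0003003\thsa-miR-dup-a\tv6\tv9\tactive
MIMAT0003003\thsa-miR-newA\tv10\t-\tactive
MIMAT0004004\thsa-miR-dup-a\tv10\t-\tactive
"""

SEQ_TSV = """\
accession\tsequence
MIMAT0000080\tUGGCUCAGUUCAGCAGGAACAG
MIMAT0000685\tCAAUCACUAACUCCACUGCCAU
MIMAT0004676\tUAGGCAGUGUCAUUAGCUGAUUG
MIMAT0001001\tAAAAGCUGGGUUGAGAGGGCGA
"""


@pytest.fixture(scope="session")
def tiny_registry(tmp_path_factory):
    d = tmp_path_factory.mktemp("registry")
    alias = d / "alias.tsv"
    seqs = d / "mature.tsv"
    alias.write_text(ALIAS_TSV)
    seqs.write_text(SEQ_TSV)
    return mv.load_registry(alias, seqs)


def make_store(pred_rows, val_rows=(), algorithms=("A", "B", "C")):
    """Build a Store directly from (mirna, gene, algorithm) triples."""
    pred = pd.DataFrame(pred_rows, columns=["mirna_accession", "gene_symbol", "algorithm_id"])
    pred["score"] = pd.NA
    val = pd.DataFrame(list(val_rows), columns=["mirna_accession", "gene_symbol", "source"])
    return mv.Store(pred, val, algorithms=list(algorithms))


@pytest.fixture()
def small_store():
    rows = [
        ("m1", "g1", "A"), ("m1", "g1", "B"), ("m1", "g1", "C"),  # hit 3
        ("m1", "g2", "A"),                                        # hit 1
        ("m2", "g1", "A"), ("m2", "g1", "B"),                     # hit 2
        ("m2", "g3", "B"),
        ("m3", "g3", "C"),
    ]
    val = [("m4", "g4", "VDB1"), ("m1", "g1", "VDB1")]
    return make_store(rows, val)


@pytest.fixture(scope="session")
def default_fixture():
    """The standard synthetic fixture (seeded, no planted signal)."""
    return mv.generate_fixture(mv.FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def default_store(default_fixture):
    return default_fixture.store()


@pytest.fixture(scope="session")
def planted_fixture():
    """Standard fixture with the default planted enriched pathway (strength 0.8)."""
    return mv.generate_fixture(mv.planted_spec(seed=0))
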