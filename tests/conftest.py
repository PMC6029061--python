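from pathlib import Path

import pytest

from editomics.editome_io import SequenceRecord, parse_genbank
from editomics.fixtures import FixtureSpec, make_editome, make_ppr98_like_matrix

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_editome():
    """The default synthetic editome (2 genes, 6 amino-acid-changing edits)."""
    editome, text = make_editome(FixtureSpec(seed=1))
    return editome, text


@pytest.fixture(scope="session")
def golden_text():
    return (DATA / "golden_editome.gb").read_text()


@pytest.fixture(scope="session")
def ppr98_matrix():
    return make_ppr98_like_matrix()


@pytest.fixture()
def mixed_editome():
    """Editome with minus-strand genes and an inverted-repeat duplicate."""
    editome, text = make_editome(
        FixtureSpec(seed=4, n_genes=3, edits_per_gene=3,
                    minus_strand_fraction=0.5, ir_duplication=True)
    )
    return editome, text


@pytest.fixture()
def self_query(default_editome):
    editome, _ = default_editome
    return SequenceRecord(id="selfquery", seq=editome.records[0].seq)
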