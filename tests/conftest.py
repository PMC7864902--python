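import numpy as np
import pytest

from protract.enrichment import ContingencyTable
from protract.ppt_scan import GeneSet, PPTProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def published_table():
    """The 2x2 table from the human gene-set analysis: 198/685 vs 4366/17981."""
    return ContingencyTable(a=198, b=487, c=4366, d=13615)


@pytest.fixture
def small_profiles():
    def make(pid, n, longest, total, seq_length=500):
        return PPTProfile(pid, seq_length, n, longest, total)

    return [
        make("G1", 2, 9, 30),
        make("G2", 3, 4, 7),
        make("G3", 1, 4, 4),
        make("G4", 0, 0, 0),
        make("B1", 1, 3, 3),
        make("B2", 1, 5, 5),
        make("B3", 0, 0, 0),
        make("B4", 0, 0, 0),
        make("B5", 0, 0, 0),
        make("B6", 0, 0, 0),
    ]


@pytest.fixture
def small_gene_set():
    return GeneSet(name="set", members=frozenset({"G1", "G2", "G3", "G4"}))


@pytest.fixture
def fasta_file(tmp_path):
    def write(records):
        path = tmp_path / "proteome.fasta"
        with open(path, "w") as fh:
            for pid, seq in records:
                fh.write(f">{pid}\n{seq}\n")
        return path

    return write
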