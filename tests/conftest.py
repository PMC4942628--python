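import numpy as np
import pytest

from lypred import ProteinRecord, default_table
from lypred.seqio import AMINO_ACIDS


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_sequence(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture()
def random_records(rng):
    def make(n, lo=12, hi=200):
        return [
            ProteinRecord(id=f"s{k}", sequence=random_sequence(rng, int(rng.integers(lo, hi + 1))))
            for k in range(n)
        ]

    return make


@pytest.fixture()
def fasta_file(tmp_path):
    def write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write
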