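import numpy as np
import pytest

from seedscape.fasta_io import ProteinDatabase, ProteinRecord
from seedscape.synthetic_data import load_reference_table

RESIDUES = list("ACDEFGHIKLMNPQRSTVWY")


def random_sequence(rng: np.random.Generator, length: int, kr_rich: bool = True) -> str:
    """Random canonical sequence; by default K/R/P-enriched so cleavage and
    suppression cases actually occur in short sequences."""
    if kr_rich:
        probs = np.ones(len(RESIDUES))
        for residue in "KRP":
            probs[RESIDUES.index(residue)] = 4.0
        probs /= probs.sum()
    else:
        probs = None
    return "".join(rng.choice(RESIDUES, size=length, p=probs))


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_db():
    return ProteinDatabase(
        records=[
            ProteinRecord(accession="A1", sequence="MKWVTFRK", description="test one"),
            ProteinRecord(accession="B2", sequence="AKPLR", description="test two"),
            ProteinRecord(accession="C3", sequence="MKWVTFRK", description="copy of one"),
        ]
    )
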