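import numpy as np
import pytest

from cscurrent.genetic_code import derive_amino_acid_table, load_codon_table


@pytest.fixture(scope="session")
def printed_table():
    return load_codon_table("printed")


@pytest.fixture(scope="session")
def corrected_table():
    return load_codon_table("corrected")


@pytest.fixture(scope="session")
def aa_table(printed_table):
    return derive_amino_acid_table(printed_table, include_stop=False)


@pytest.fixture(scope="session")
def sense_codons(printed_table):
    return sorted(e.codon for e in printed_table if not e.is_stop)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing a FASTA file from (id, seq) pairs."""

    def _write(*records, name="seqs.fa"):
        path = tmp_path / name
        path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in records))
        return path

    return _write


def random_codon_seq(rng: np.random.Generator, n: int, codons: list[str]) -> str:
    return "".join(rng.choice(codons, size=n))
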