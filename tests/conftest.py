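import random

import pytest

from crustakin.core_io import DomainAnnotation, SequenceRecord


@pytest.fixture
def pka_c1_record():
    """Catalytic-subunit-like sequence with MGNxxxxK start and FxxxW anchor."""
    residues = "MGNAAATKSSAQLDFAQLW" + "LKDEFERIKTLGTGSFGRVML" * 10
    return SequenceRecord(id="c1", residues=residues, species="Carcinus maenas",
                          phylum="Arthropoda")


@pytest.fixture
def pka_c1_annotations(pka_c1_record):
    return [DomainAnnotation(seq_id="c1", domain_name="kinase",
                             start=30, end=len(pka_c1_record), complete=True)]


def random_protein(rng: random.Random, n: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))
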