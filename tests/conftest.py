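import pytest

from hladq import DQGenotype, load_czech_table


@pytest.fixture(scope="session")
def czech_table():
    return load_czech_table()


def make_genotype(a1, a2, b1, b2, sample_id="S1"):
    return DQGenotype.from_strings(sample_id, a1, a2, b1, b2)


@pytest.fixture
def genotype_factory():
    return make_genotype
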