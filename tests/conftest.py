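import pytest

from wrkytools.pipeline import classify_gene_set
from wrkytools.sequence_io import load_gene_table
from wrkytools.synthetic_data import SynthConfig, generate_genome


@pytest.fixture(scope="session")
def gene_table():
    return load_gene_table()


@pytest.fixture(scope="session")
def synthetic_genome():
    """Default-condition synthetic genome (family design 12/5/8/13/5/9/2/7,
    9 pseudogenes, 10 defective decoys, one planted tandem pair)."""
    return generate_genome(SynthConfig(seed=3))


@pytest.fixture(scope="session")
def synthetic_classification(synthetic_genome):
    return classify_gene_set(synthetic_genome.records)
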