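import pytest

from haploscreen import ScreenSimConfig, generate_genome
from haploscreen.models import GeneModel


@pytest.fixture(scope="session")
def small_config() -> ScreenSimConfig:
    return ScreenSimConfig(
        n_chromosomes=2,
        chromosome_length=100_000,
        n_genes=20,
        n_insertions=1_000,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture
def toy_gene() -> GeneModel:
    """A forward-strand gene on chr1 with exons [100,200) and [300,400)."""
    return GeneModel("G1", "chr1", "+", ((100, 200), (300, 400)))
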