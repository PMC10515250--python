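import pytest

from bsamap import popsim
from bsamap.genome import Chromosome, GenomeModel


@pytest.fixture(scope="session")
def small_genome():
    """Three-chromosome toy genome; chrC has zero genetic length (no crossovers)."""
    return GenomeModel(
        (
            Chromosome("chrA", 10_000_000, 0.8),
            Chromosome("chrB", 8_000_000, 0.6),
            Chromosome("chrC", 5_000_000, 0.0),
        )
    )


@pytest.fixture(scope="session")
def small_variants(small_genome):
    return popsim.simulate_ems_variants(
        small_genome, 60, ("chrA", 2_000_000, "G", "T"), seed=101
    )


@pytest.fixture(scope="session")
def small_pop(small_variants, small_genome):
    return popsim.make_bc1f2(small_variants, 200, small_genome, seed=102)
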