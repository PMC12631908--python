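import numpy as np
import pytest

from satkit.synthetic import GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def default_genome():
    """One default synthetic genome shared by read-only tests."""
    genome, truth = generate_genome(GenomeSpec.default(seed=1))
    return genome, truth


@pytest.fixture(scope="session")
def chrom_lengths(default_genome):
    genome, _ = default_genome
    return {r.id: len(r.seq) for r in genome}


@pytest.fixture(scope="session")
def truth_partition(default_genome):
    _, truth = default_genome
    return truth.partition()


@pytest.fixture(scope="session")
def discovered_monomer(default_genome):
    from satkit.satellite import discover_monomer

    genome, _ = default_genome
    monomers = discover_monomer(genome)
    assert monomers
    return monomers[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
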