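import pytest

from probemap import ConvertedGenome
from probemap.synthetic import generate_genome, plant_probes


@pytest.fixture(scope="session")
def small_genome():
    """Two 50-kb chromosomes with planted CGIs, enhancers and transcripts."""
    return generate_genome(n_chrom=2, length=50_000, seed=11)


@pytest.fixture(scope="session")
def clean_planted(small_genome):
    """Probes planted with no mutations and no duplicates."""
    return plant_probes(small_genome, n_probes=60, mutation_rate=0.0,
                        duplicate_fraction=0.0, seed=12)


@pytest.fixture(scope="session")
def noisy_planted(small_genome):
    """Probes planted with mutations and a 20% duplicated fraction."""
    return plant_probes(small_genome, n_probes=100, mutation_rate=0.02,
                        duplicate_fraction=0.2, seed=13)


@pytest.fixture(scope="session")
def clean_converted(clean_planted):
    return ConvertedGenome(clean_planted.genome.seqs)


@pytest.fixture(scope="session")
def noisy_converted(noisy_planted):
    return ConvertedGenome(noisy_planted.genome.seqs)
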