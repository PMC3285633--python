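import numpy as np
import pytest

from mgsim import CommunityProfile, Genome, build_rank_abundance, generate_synthetic_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genomes() -> list[Genome]:
    """Three 20 kb synthetic genomes."""
    return [
        generate_synthetic_genome(20_000, 0.5, seed=100 + i, genome_id=f"g{i}")
        for i in range(3)
    ]


@pytest.fixture(scope="session")
def uniform_profile(small_genomes) -> CommunityProfile:
    return build_rank_abundance(
        len(small_genomes), "uniform", genome_ids=[g.id for g in small_genomes]
    )
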