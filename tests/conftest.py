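import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from symbiorate import (
    CdsFeature,
    GenomeSequence,
    SimulationConfig,
    build_codon_position_map,
)


@pytest.fixture
def toy_genome():
    # 30 bp: two CDSs [0,6)+ and [9,18)-, rest intergenic
    seq = "ATGAAATTTGCGCGCGCATAAACGTACGTA"
    return GenomeSequence("c1", seq, "linear")


@pytest.fixture
def toy_cds():
    return [
        CdsFeature("c1", 0, 6, "+", 0, "g1", "p1"),
        CdsFeature("c1", 9, 18, "-", 0, "g2", "p2"),
    ]


@pytest.fixture
def toy_cpmap(toy_genome, toy_cds):
    return build_codon_position_map([toy_genome], toy_cds)


@pytest.fixture(scope="session")
def small_sim_config():
    return SimulationConfig(genome_length=100_000, n_cds=80, seed=11)


@pytest.fixture(scope="session")
def small_fixture_set(small_sim_config):
    from symbiorate import generate_fixture_set

    return generate_fixture_set(small_sim_config)


@pytest.fixture
def full_coverage_tracks():
    def make(genome, depth=10, n=1):
        from symbiorate import DepthTrack

        return [
            DepthTrack(f"lib{i + 1}", genome.contig_id, np.full(genome.length, depth))
            for i in range(n)
        ]

    return make
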