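import numpy as np
import pytest

from npomics.config import PipelineConfig, SimConfig
from npomics.simulate import simulate


@pytest.fixture(scope="session")
def pipeline_cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """8 genomes, planted structure, fixed seed; shared across tests."""
    return simulate(SimConfig(n_genomes=8, seed=11))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free dataset: exact family recovery is possible."""
    cfg = SimConfig(n_genomes=6, domain_mutation_rate=0.0,
                    fingerprint_flip_rate=0.0, seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def calibration_dataset():
    """Shared archetypes only, so every family has many members and any
    above-gap merge mixes enough chemistry to break homogeneity."""
    cfg = SimConfig(n_genomes=8, n_shared_archetypes=6,
                    n_private_archetypes_per_genome=0, seed=23)
    return simulate(cfg)


@pytest.fixture(scope="session")
def planted_diversity():
    """5 genomes rich in private families among 20 clones.

    Noise-free at the BGC level so the planted high/low split is exact;
    returns (dataset, presence matrix).
    """
    from npomics.diversity import presence_matrix
    from npomics.families import build_partition
    from npomics.similarity import pairwise_distances

    cfg = SimConfig(n_genomes=25, n_shared_archetypes=1,
                    n_private_archetypes_per_genome=45,
                    n_diverse_genomes=5, domain_mutation_rate=0.0,
                    fingerprint_flip_rate=0.0, seed=13)
    ds = simulate(cfg)
    dm = pairwise_distances(ds.bgcs)
    part = build_partition(dm, 0.30)
    pm = presence_matrix(part, {b.id: b.genome_id for b in ds.bgcs})
    return ds, pm
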