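import numpy as np
import pytest

from dgeprof import synthetic, taglib


@pytest.fixture
def small_config():
    return synthetic.SimulationConfig(
        n_genes_a=30,
        n_genes_d=30,
        homeolog_fraction=0.0,
        n_timepoints=6,
        library_size=5000,
        error_rate=0.0,
        seed=11,
        abundance_sigma=0.5,
    )


@pytest.fixture
def small_genomes(small_config):
    return synthetic.simulate_genomes(small_config)


@pytest.fixture
def small_truth(small_genomes, small_config):
    genes = [g for g, _ in small_genomes.genes_a] + [
        g for g, _ in small_genomes.genes_d
    ]
    return synthetic.simulate_trajectories(genes, small_config)


def random_tag(rng: np.random.Generator) -> str:
    suffix = "".join(rng.choice(list("ACGT"), size=taglib.SUFFIX_LENGTH))
    return taglib.ANCHOR + suffix


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
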