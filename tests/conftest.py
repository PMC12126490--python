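import numpy as np
import pytest

from ervscape import SimulationConfig, generate_repeat_annotation, simulate_count_table


@pytest.fixture
def small_config():
    """3 families x 12 integrations, one ChIP dataset, planted 4x at fam01."""
    return SimulationConfig(
        seed=11,
        n_families=3,
        loci_per_family=12,
        genome_length=600_000,
        enrichment_factors={"ds1": {"fam01": 4.0, "fam02": 1.0, "fam03": 1.0}},
        library_sizes={"ds1": 10_000_000},
        orphan_fraction=0.5,
    )


@pytest.fixture
def small_annotation(small_config):
    return generate_repeat_annotation(small_config)


@pytest.fixture
def small_counts(small_config, small_annotation):
    return simulate_count_table(small_annotation, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
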