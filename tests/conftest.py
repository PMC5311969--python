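import pytest

from honeyforage.synthetic_data import (
    SimulationConfig,
    default_study,
    simulate_reads,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_reference():
    """A small hierarchical library: 3 families x 2 genera x 2 species."""
    return simulate_reference(
        SimulationConfig(n_families=3, genera_per_family=2, species_per_genus=2, seed=11)
    )


@pytest.fixture(scope="session")
def small_study():
    """A miniature 3-hive x 2-month study with 300 pairs per sample."""
    return default_study(seed=7, n_read_pairs=300)


@pytest.fixture(scope="session")
def small_study_batches(small_study):
    batches = []
    for mixture in small_study.mixtures:
        batch, _ = simulate_reads(small_study.reference, mixture)
        hive, month = mixture.sample_id.split("_", 1)
        batches.append((hive, month, batch))
    return batches
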