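import numpy as np
import pytest

from rpb1kit.simulate import (
    SimulationConfig,
    simulate_community_reads,
    simulate_reference_set,
)


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured simulation: 6 species, 6 samples."""
    return SimulationConfig(
        n_species=6,
        isolates_per_species=2,
        reads_per_sample=120,
        plots_per_treatment=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return simulate_reference_set(small_config)


@pytest.fixture(scope="session")
def small_community(small_config, small_reference):
    ref, _ = small_reference
    return simulate_community_reads(small_config, ref)


@pytest.fixture(scope="session")
def clean_config():
    """No errors, no chimeras, no intra-species divergence, fixed read length."""
    return SimulationConfig(
        n_species=4,
        isolates_per_species=1,
        intra_species_divergence=0.0,
        substitution_error_rate=0.0,
        homopolymer_indel_base_rate=0.0,
        chimera_rate=0.0,
        include_offtarget=False,
        read_length=(300, 300, 300),
        reads_per_sample=60,
        plots_per_treatment=2,
        seed=5,
    )


@pytest.fixture(scope="session")
def clean_reference(clean_config):
    return simulate_reference_set(clean_config)


@pytest.fixture(scope="session")
def clean_community(clean_config, clean_reference):
    ref, _ = clean_reference
    return simulate_community_reads(clean_config, ref)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
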