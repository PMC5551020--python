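import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from canegbs.simulate import SimConfig


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast, fully deterministic study: 3 contigs, 400 loci, 4-of-each panel."""
    return SimConfig(
        rng_seed=42,
        n_sequences=3,
        seq_length=12_000,
        spacing_mean=900.0,
        n_loci=400,
        n_reads=4000,
        n_regions=300,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    from canegbs.simulate import simulate_genome

    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_genome):
    from canegbs.simulate import simulate_allele_reads, simulate_genotypes

    genome, _ = small_genome
    truth = simulate_genotypes(small_config, genome)
    return simulate_allele_reads(truth, small_config)
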