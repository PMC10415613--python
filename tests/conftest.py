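import pytest

from juncscope.simulate import SimConfig, make_genome_annotation, simulate_counts


@pytest.fixture(scope="session")
def truth():
    """One small deterministic simulated cohort shared across tests."""
    return make_genome_annotation(SimConfig(seed=42, n_genes=10))


@pytest.fixture(scope="session")
def counts(truth):
    return simulate_counts(truth)


@pytest.fixture(scope="session")
def genome(truth):
    return truth.genome
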