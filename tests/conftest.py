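import pytest

from cgsplice.synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_cg_readthrough,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_gene_pairs=8, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Annotation + genome + planted CG evidence shared across tests."""
    ann, genome = simulate_annotation(small_config)
    junctions, coverage, planted = simulate_cg_readthrough(
        small_config, ann, seed=43
    )
    return {
        "config": small_config,
        "ann": ann,
        "genome": genome,
        "junctions": junctions,
        "coverage": coverage,
        "planted": planted,
    }
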