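"""Shared fixtures: small simulated genome sets reused across test modules."""

import pytest

from genosig.synthetic_data import (
    PlantSpec,
    SimulationConfig,
    simulate_ancestor,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_ancestor():
    """Default-plan ancestor genome (clean, all features planted)."""
    cfg = SimulationConfig(seed=101, genome_length_bp=90_000, gene_count=100)
    return simulate_ancestor(cfg)


@pytest.fixture(scope="session")
def neutral_cfg_factory():
    """Neutral-only configs for divergence-calibration tests."""

    def make(seed, p, length=50_000, genes=40, indel_rate=0.0, n_genomes=2):
        return SimulationConfig(
            seed=seed, n_genomes=n_genomes, genome_length_bp=length,
            gene_count=genes, substitution_rate=p, indel_rate=indel_rate,
            feature_plan=[],
        )

    return make


@pytest.fixture(scope="session")
def recovery_dataset():
    """Five genomes at moderate divergence (p = 0.1 per root-to-leaf path)
    with the default planted-feature plan; truth table attached."""
    cfg = SimulationConfig(
        seed=202, genome_length_bp=90_000, gene_count=100,
        substitution_rate=0.10, indel_rate=0.0001,
    )
    return simulate_dataset(cfg)
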