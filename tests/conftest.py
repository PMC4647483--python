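"""Shared fixtures: small synthetic genomes and derived inputs.

Everything is generated at test time from fixed seeds; no data files are
stored beyond the packaged published table.
"""

from __future__ import annotations

import dataclasses

import pytest

from rbctx.synthetic_data import SimulationConfig, generate_genome, simulate_reads


SMALL = SimulationConfig(
    seed=11,
    n_chroms=2,
    chrom_length=1_500_000,
    n_genes=40,
    n_pre_mirna_loci=12,
    n_samples=3,
    reads_per_sample=2_000,
    n_known_mirnas=4,
    n_putative_mirnas=4,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SMALL


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_reads(small_genome):
    return simulate_reads(small_genome)


def config_with(**overrides) -> SimulationConfig:
    return dataclasses.replace(SMALL, **overrides)
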