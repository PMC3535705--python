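"""Shared fixtures: one desk-scale simulated genome and a pair of lanes
(captured / enrichment-failed) reused across module tests."""

from __future__ import annotations

import numpy as np
import pytest

from methylcap.genome_index import build_genome_index_from_sequences
from methylcap.simulate import (
    SimConfig,
    draw_methylation,
    simulate_genome,
    simulate_lane,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    return simulate_genome(sim_config)


@pytest.fixture(scope="session")
def sim_index(sim_genome):
    return sim_genome.build_index()


@pytest.fixture(scope="session")
def sim_methylation(sim_genome):
    return draw_methylation(sim_genome, 0.5, np.random.default_rng(2))


@pytest.fixture(scope="session")
def captured_sim_lane(sim_genome, sim_methylation):
    return simulate_lane(sim_genome, sim_methylation, mode="captured", seed=3)


@pytest.fixture(scope="session")
def failed_sim_lane(sim_genome, sim_methylation):
    return simulate_lane(sim_genome, sim_methylation, mode="failed", seed=3)


@pytest.fixture(scope="session")
def captured_lane(captured_sim_lane, sim_index):
    return captured_sim_lane.to_lane(sim_index)


@pytest.fixture(scope="session")
def failed_lane(failed_sim_lane, sim_index):
    return failed_sim_lane.to_lane(sim_index)


def tiny_index(sequence: str, bin_size: int = 500, name: str = "chr1"):
    return build_genome_index_from_sequences({name: sequence}, bin_size=bin_size)


@pytest.fixture
def make_index():
    return tiny_index
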