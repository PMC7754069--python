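"""Shared fixtures: one default simulation, computed once per session."""

from __future__ import annotations

import pytest

from dmrecon import (
    call_junctions_from_reads,
    make_reference,
    make_truth,
    run_all,
    simulate_cn_profile,
    simulate_junction_reads,
)
from dmrecon.config import PipelineConfig, SimConfig


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def genome(sim_config):
    return make_reference(sim_config)


@pytest.fixture(scope="session")
def truth(sim_config, genome):
    t = make_truth(sim_config)
    # sampling the reads fills in the truth junctions' insertion sequences
    simulate_junction_reads(t, sim_config, genome)
    return t


@pytest.fixture(scope="session")
def reads(sim_config, genome):
    t = make_truth(sim_config)
    return simulate_junction_reads(t, sim_config, genome)


@pytest.fixture(scope="session")
def noiseless_config() -> SimConfig:
    cfg = SimConfig(seed=1)
    cfg.log2_noise_sd = 0.0
    return cfg


@pytest.fixture(scope="session")
def noiseless_profile(noiseless_config):
    t = make_truth(noiseless_config)
    return simulate_cn_profile(t, noiseless_config)


@pytest.fixture(scope="session")
def junction_calls(reads, genome, truth):
    segs = []
    for name, s in truth.segments.items():
        s.tier = truth.multiplicity(name)
        segs.append(s)
    return call_junctions_from_reads(reads, genome, segments=segs)


@pytest.fixture(scope="session")
def default_summary():
    return run_all(PipelineConfig(seed=1), write=False)
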