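"""Shared fixtures: toy structures and the default simulated experiment."""

from __future__ import annotations

import numpy as np
import pytest

import damkit
from damkit import SimConfig


@pytest.fixture
def toy_genome():
    """Length-20 chromosome with GATC motifs at 4 and 12.

    Fragment map (cut = motif start + 2): [0,6), [6,14), [14,20).
    """
    seq = "AAAA" + "GATC" + "AAAA" + "GATC" + "AAAA"
    assert len(seq) == 20
    return {"chr_toy": seq}


@pytest.fixture
def toy_map(toy_genome):
    return damkit.build_fragment_map(toy_genome)


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions: 200 kb chromosome, ~190 bp GATC
    spacing, 40 planted binding fragments, p_bound 0.8 / p_open 0.05,
    3 fusion + 3 Dam-only samples of 50,000 molecules, seed 1."""
    cfg = SimConfig(seed=1)
    genome, fmap, truth, reads_by_id, roles = damkit.simulate_experiment(cfg)
    return cfg, genome, fmap, truth, reads_by_id, roles


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    """Full analysis of the default simulation (shared: it is expensive)."""
    _cfg, genome, _fmap, _truth, reads_by_id, roles = default_sim
    return damkit.run_analysis(genome, reads_by_id, roles)


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast experiment for pipeline-level tests."""
    cfg = SimConfig(
        chromosome_length=30_000, n_binding_sites=8, n_molecules=4_000, seed=11
    )
    genome, fmap, truth, reads_by_id, roles = damkit.simulate_experiment(
        cfg, n_fusion=2, n_damonly=2
    )
    return cfg, genome, fmap, truth, reads_by_id, roles
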