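"""Shared fixtures: study-scale SELEX simulations are expensive, so one
pair of replicate selections (and their enrichment tables) is computed once
per session and reused by the SELEX, genome-scan, and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from stalkscape import selex, simulate
from stalkscape.simulate import SimConfig

#: study-scale SELEX conditions: 101 bp ligands, 4 rounds, 20k reads/round
SELEX_SEED = 5
NULL_SHUFFLES = 20


@pytest.fixture(scope="session")
def selex_cfg() -> SimConfig:
    return SimConfig(seed=SELEX_SEED)


def _enrich(libs, shuffle_seed):
    r4 = selex.dedupe_reads(libs[-1])
    null = selex.shuffle_library(r4, seed=shuffle_seed, repeats=NULL_SHUFFLES)
    return r4, null, selex.kmer_enrichment(r4, null, k=10)


@pytest.fixture(scope="session")
def selex_run(selex_cfg):
    """First replicate: libraries, deduped round 4, null, enrichment."""
    libs, pwm = simulate.simulate_selex(selex_cfg)
    r4, null, ke = _enrich(libs, shuffle_seed=77)
    return {"libs": libs, "pwm": pwm, "r4": r4, "null": null, "ke": ke}


@pytest.fixture(scope="session")
def selex_replicate(selex_cfg):
    """Independent second replicate of the same selection."""
    libs, _ = simulate.simulate_selex(selex_cfg, replicate=1)
    r4, null, ke = _enrich(libs, shuffle_seed=78)
    return {"libs": libs, "r4": r4, "null": null, "ke": ke}


@pytest.fixture(scope="session")
def study_expression():
    """A default two-replicate 19-internode expression simulation."""
    cfg = SimConfig(seed=1, n_genes=2000)
    em, meta, truth = simulate.simulate_expression(cfg)
    return cfg, em, meta, truth


@pytest.fixture(scope="session")
def module_sim():
    """Planted-module expression with trait coupling (1500 genes)."""
    cfg = SimConfig(seed=3, n_genes=1500)
    em, labels, factors = simulate.simulate_module_expression(cfg)
    traits = simulate.simulate_traits(cfg, factors)
    return cfg, em, labels, factors, traits


def random_reads(rng: np.random.Generator, n: int, length: int) -> list[str]:
    arr = rng.integers(0, 4, (n, length), dtype=np.uint8)
    return selex.decode_reads(arr)
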