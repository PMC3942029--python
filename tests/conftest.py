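"""Shared fixtures: the canonical synthetic scenarios, generated once per
session (everything is seeded and in-memory; no data files)."""

from __future__ import annotations

import numpy as np
import pytest

from mulescan import fixtures


@pytest.fixture(scope="session")
def families5():
    """Five-family protein set with truth (seed 1)."""
    records, truth = fixtures.make_families5(1)
    seqs = {r.id: str(r.seq) for r in records}
    return seqs, truth


@pytest.fixture(scope="session")
def uniform_te():
    """Uniform-random multi-copy insertions (seed 5): genome string, truth
    table, planted elements."""
    genome, truth, tes = fixtures.make_uniform(5)
    return str(genome.seq), truth, tes


@pytest.fixture(scope="session")
def promoter_te():
    """Promoter-targeted insertions at reduced scale (100 sites, seed 7)."""
    genome, truth, tes = fixtures.make_promoter_bias(
        7, n_insertions=100, genome_length=400_000)
    return str(genome.seq), truth, tes


@pytest.fixture(scope="session")
def promoter_te_full():
    """Promoter-targeted insertions at full scale (500 sites, seed 7)."""
    genome, truth, tes = fixtures.make_promoter_bias(7, n_insertions=500)
    return str(genome.seq), truth, tes


@pytest.fixture(scope="session")
def chain_db():
    """Transitive-homology chain database (seed 0)."""
    records, truth = fixtures.make_chain(0)
    return {r.id: str(r.seq) for r in records}, truth.members


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
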