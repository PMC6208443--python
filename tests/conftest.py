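"""Shared fixtures: a small deterministic synthetic genome and derived data.

Everything is generated in-process; no files ship with the repo.
"""

import numpy as np
import pytest

from hetkit import io as hio
from hetkit import synthetic


@pytest.fixture(scope="session")
def small_spec():
    return synthetic.GenomeSpec(
        chromosomes=(("chr1", 300_000), ("chr2", 300_000)),
        seed=11,
        tes_per_mb=80,
        genes_per_mb=120,
    )


@pytest.fixture(scope="session")
def genome(small_spec):
    return synthetic.generate_genome(small_spec)


@pytest.fixture(scope="session")
def model(genome):
    return synthetic.MethylomeModel(planted_dmrs=synthetic.plant_dmrs(genome))


@pytest.fixture(scope="session")
def methylomes(genome, model):
    wt = synthetic.simulate_methylome(genome, model, "wildtype", seed=11)
    mut = synthetic.simulate_methylome(genome, model, "mutant", seed=11)
    return wt, mut


@pytest.fixture(scope="session")
def chg_bins(genome, methylomes):
    wt, mut = methylomes
    return (
        hio.aggregate_bins(wt, genome.chrom_sizes, "CHG"),
        hio.aggregate_bins(mut, genome.chrom_sizes, "CHG"),
    )


@pytest.fixture(scope="session")
def chip(genome):
    return synthetic.simulate_chip(genome, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
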