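import numpy as np
import pytest

import rhinotools as rt
from rhinotools import simulate as sim
from rhinotools.tiles import compute_mappability


@pytest.fixture(scope="session")
def genome():
    return sim.sim_genome(seed=11)


@pytest.fixture(scope="session")
def tiles(genome):
    ts = rt.make_tiles({c: len(genome.sequences[c]) for c in genome.nuclear_chroms})
    compute_mappability(ts, genome.mappable_blocks())
    return ts


@pytest.fixture(scope="session")
def chip_data(genome):
    """Medium-depth ChIP/input simulation shared across tests."""
    chip, inp, truth = sim.sim_chip(genome, n_reads=100_000, seed=11)
    return chip, inp, truth


@pytest.fixture(scope="session")
def srna_data(genome):
    fastq, truth = sim.sim_srna(genome, seed=11)
    return fastq, truth


@pytest.fixture(scope="session")
def srna_results(genome, tiles, srna_data):
    fastq, truth = srna_data
    cfg = rt.PipelineConfig(rng_seed=11)
    return {
        geno: rt.run_smallrna_pipeline(
            cfg,
            fastq[geno],
            genome.sequences,
            genome.annotation_bed(),
            genome.te_consensus,
            genome.clusters,
            tiles=tiles,
        )
        for geno in fastq
    }
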