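import numpy as np
import pytest

from pbtrace.genome import (
    PlantedInsertion,
    default_construct,
    insert_transgene,
    make_toy_genome,
)
from pbtrace.reads import ReadSimParams, simulate_paired_reads


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(2, [20000, 15000], gc_fraction=0.42, seed=7)


@pytest.fixture(scope="session")
def construct():
    return default_construct(seed=99, length=2000)


@pytest.fixture(scope="session")
def planted(toy_genome, construct):
    """Genome with one reverse-orientation insertion at a TTAA site."""
    chrom = "chr1"
    pos = toy_genome.chromosomes[chrom].find("TTAA", 8000)
    site = PlantedInsertion(chrom, pos, "reverse")
    modified, truth = insert_transgene(toy_genome, construct, site)
    return modified, truth


@pytest.fixture(scope="session")
def planted_reads(planted):
    modified, truth = planted
    params = ReadSimParams(coverage=20.0, error_rate=0.001, seed=11)
    pairs, table = simulate_paired_reads(modified, params)
    return pairs, table, truth
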