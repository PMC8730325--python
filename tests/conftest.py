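import numpy as np
import pytest

import pirnakit as pk
from pirnakit.simulate import SimConfig, simulate_genome, simulate_reads

# Scaled-down study conditions: every statistical parameter (fractions,
# biases, length distributions, mutation rate) is at its default; only the
# genome size and read counts are reduced to keep the suite fast.
SCALED_KW = dict(
    genome_len=200_000,
    n_transposon_families=4,
    copies_per_family=10,
    n_genes=25,
    n_pirna=12_000,
    n_mirna=5_000,
    n_degradation=1_200,
)

SEED = 42


@pytest.fixture(scope="session")
def sim_library():
    """One simulated library under default statistical conditions:
    (config, genome, features, reads, truth)."""
    cfg = SimConfig(seed=SEED, **SCALED_KW)
    genome, features = simulate_genome(cfg)
    reads, truth = simulate_reads(cfg, genome, features)
    return cfg, genome, features, reads, truth


@pytest.fixture(scope="session")
def sim_mapped(sim_library):
    """The simulated library mapped read-by-read (ids preserved so truth
    labels can be joined): (config, genome, features, reads, truth, aln)."""
    cfg, genome, features, reads, truth = sim_library
    index = pk.ExactIndex(genome, 18)
    aln = pk.map_reads(reads, index)
    return cfg, genome, features, reads, truth, aln


@pytest.fixture(scope="session")
def sim_classified(sim_mapped):
    cfg, genome, features, reads, truth, aln = sim_mapped
    cr = pk.annotate_reads(aln, features.build_index())
    return cfg, genome, features, reads, truth, aln, cr


@pytest.fixture
def tiny_genome():
    """A handcrafted two-contig genome for exact-coordinate tests."""
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    c1 = rng.choice(bases, size=600).tobytes().decode()
    c2 = rng.choice(bases, size=300).tobytes().decode()
    return pk.Genome({"c1": c1, "c2": c2})
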