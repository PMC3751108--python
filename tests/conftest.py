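import numpy as np
import pytest

from acetylscan.coverage import ReadSet
from acetylscan.genome_model import GeneAnnotation
from acetylscan.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture
def toy_gene():
    """Plus-strand gene with tss=1000, tts=1999; promoter [0, 1000) at 1 kb."""
    return GeneAnnotation("geneA", "chr1", "+", 1000, 2000)


@pytest.fixture
def toy_reads():
    """The hand-enumerated classification example: two promoter reads (one
    spanning the TSS), two gene-body reads (the same spanning read), one
    intergenic read."""
    starts = [500, 1500, 990, 3000]
    return ReadSet(["chr1"] * 4, starts, [s + 50 for s in starts], sample_label="toy")


def random_instance(rng, max_genes=5, max_reads=50, span=20000):
    """A small random genome + read set for oracle comparisons."""
    n_genes = int(rng.integers(1, max_genes + 1))
    genes = []
    pos = int(rng.integers(0, 2000))
    for i in range(n_genes):
        pos += int(rng.integers(500, 3000))
        length = int(rng.integers(200, 2500))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((f"g{i}", "chr1", strand, pos, pos + length))
        pos += length
    n_reads = int(rng.integers(0, max_reads + 1))
    reads = []
    for _ in range(n_reads):
        s = int(rng.integers(0, span))
        reads.append(("chr1", s, s + int(rng.integers(20, 80))))
    return reads, genes


def to_objects(reads, genes):
    rs = ReadSet(
        [c for c, _, _ in reads],
        [s for _, s, _ in reads],
        [e for _, _, e in reads],
    )
    gs = [GeneAnnotation(*g) for g in genes]
    return rs, gs


@pytest.fixture(scope="session")
def default_study():
    """The reference synthetic study at default generator settings."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_study():
    """A down-scaled study for fast module-level tests."""
    return simulate_study(SimulationConfig(seed=3, n_genes=300, n_planted=20))


@pytest.fixture(scope="session")
def boost_study():
    """Default conditions with the TFBS proximal-depletion boost enabled."""
    return simulate_study(SimulationConfig(seed=1, tfbs_boost_factor=2.0))
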