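import pytest

from mbdscan.io import GeneModel, ReadAlignment
from mbdscan.simulate import (SimulationConfig, simulate_landscape,
                              simulate_reads)


@pytest.fixture
def chrom_sizes():
    return {"chr1": 1_000_000, "chr2": 500_000}


@pytest.fixture
def landscape(chrom_sizes):
    return simulate_landscape(chrom_sizes, 20, 0.6, (800, 1200), rng_seed=11,
                              min_gap=2000)


@pytest.fixture
def enriched_reads(landscape):
    cfg = SimulationConfig(enrichment_factor=8.0, n_reads=60_000, rng_seed=5)
    return simulate_reads(landscape, "control", cfg)


@pytest.fixture
def gene_models():
    """Two-strand fixture on one chromosome: a '+' gene with two exons and a
    '-' gene downstream, far enough apart for unambiguous feature classes."""
    return [
        GeneModel("geneA", "chr1", "+", tss=100_000, tts=140_000,
                  exons=[(100_000, 101_000), (139_000, 140_000)]),
        GeneModel("geneB", "chr1", "-", tss=400_000, tts=350_000,
                  exons=[(350_000, 352_000), (398_000, 400_000)]),
    ]


def make_reads(positions, chrom="chr1", strand="+", length=100):
    """Reads whose 5' coordinate equals each requested position."""
    reads = []
    for p in positions:
        if strand == "+":
            reads.append(ReadAlignment(chrom, p, p + length, "+"))
        else:
            reads.append(ReadAlignment(chrom, p - length + 1, p + 1, "-"))
    return reads
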