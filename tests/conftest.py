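import numpy as np
import pytest

from cohic.genome import BinGrid, Gene, GenomicInterval, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return BinGrid(5000, {"chr1": 100_000})


def make_gene(gid, chrom, start, end, strand="+", biotype="protein_coding"):
    return Gene(gid, GenomicInterval(chrom, start, end, strand), biotype)


def make_peaks(mark, triples):
    return PeakSet(mark, [GenomicInterval(c, s, e) for c, s, e in triples])
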