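import numpy as np
import pytest

from cistromix.core import GeneModel, GenomicInterval, Peak, PeakSet


def mk_peak(start, end, summit=None, fdr=5.0, td=20.0, pid=None, chrom="chr1",
            source=""):
    if summit is None:
        summit = (start + end) // 2
    if pid is None:
        pid = f"{chrom}:{start}-{end}"
    return Peak(GenomicInterval(chrom, start, end), summit, fdr, td, pid, source)


def mk_gene(gene_id, tss, tes, strand="+", chrom="chr1", exons=None, utr5=None):
    return GeneModel(gene_id, chrom, strand, tss, tes, exons or [], utr5)


@pytest.fixture
def rng():
    return np.random.default_rng(20150326)


@pytest.fixture
def peak_factory():
    return mk_peak


@pytest.fixture
def gene_factory():
    return mk_gene


def random_peak_set(rng, n, label, span=100_000, chroms=("chr1", "chr2")):
    peaks = []
    for i in range(n):
        chrom = str(rng.choice(list(chroms)))
        start = int(rng.integers(0, span))
        length = int(rng.integers(50, 1000))
        summit = start + int(rng.integers(0, length))
        fdr = float(rng.uniform(0, 20))
        td = float(rng.uniform(0, 40))
        peaks.append(
            Peak(GenomicInterval(chrom, start, start + length), summit, fdr, td,
                 f"{label}_{i}", label)
        )
    return PeakSet(peaks, label=label)
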