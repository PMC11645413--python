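import numpy as np
import pytest

from cistromere.genome import Genome
from cistromere.intervals import GenomicInterval, PeakSet
from cistromere.motifs import canonical_are_pwm


@pytest.fixture(scope="session")
def are_pwm():
    return canonical_are_pwm()


@pytest.fixture(scope="session")
def are_threshold(are_pwm):
    return are_pwm.threshold_for_fpr()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def poly_t_genome():
    """A motif-free canvas: the ARE model cannot hit poly-T."""
    return Genome({"chr1": "T" * 20000})


def random_peakset(rng, n, chrom="chr1", span=1000, max_len=60, name=""):
    starts = rng.integers(0, span - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return PeakSet(
        [
            GenomicInterval(chrom, int(s), int(s + l))
            for s, l in zip(starts, lengths)
        ],
        sample_id=name,
    )


def coverage(peaks, chrom="chr1", span=1000):
    """Per-base boolean coverage array (brute-force oracle helper)."""
    cov = np.zeros(span, dtype=bool)
    for iv in peaks:
        if iv.chrom == chrom:
            cov[iv.start:min(iv.end, span)] = True
    return cov
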