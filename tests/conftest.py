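import numpy as np
import pytest

from corepeak.genome_model import GenomicInterval, Peak, Transcript


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_peak(chrom, start, end, name="p", summit=None, p=1.0):
    width = end - start
    return Peak(
        GenomicInterval(chrom, start, end),
        name=name,
        summit_offset=width // 2 if summit is None else summit - start,
        neg_log10_p=p,
    )


def make_transcript(chrom, start, end, strand="+", tid="tx", gid=None):
    return Transcript(
        GenomicInterval(chrom, start, end),
        strand=strand,
        transcript_id=tid,
        gene_id=gid or tid,
    )


@pytest.fixture
def peak_factory():
    return make_peak


@pytest.fixture
def transcript_factory():
    return make_transcript
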