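import numpy as np
import pytest

from scc2xpress.genomic_core import AlignedRead, GenomicInterval, TranscriptModel


@pytest.fixture
def toy_sizes():
    return {"chr1": 20, "chr2": 50}


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_read(chrom, start, end, strand="+", blocks=None, sample="s1"):
    iv = GenomicInterval(chrom, start, end, strand)
    blk = tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks) if blocks else ()
    return AlignedRead(interval=iv, blocks=blk, sample_id=sample)


@pytest.fixture
def two_exon_transcript():
    # + strand: exon 1000-1400, intron 1400-1600, exon 1600-2000
    return TranscriptModel(
        "tx1",
        (
            GenomicInterval("chr2", 0, 10, "+"),
            GenomicInterval("chr2", 20, 35, "+"),
        ),
    )
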