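import numpy as np
import pytest
from hypothesis import settings

from racenet import pipeline
from racenet.core import GeneModel, GenomicInterval

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pipeline_result():
    """One full synthetic pipeline run shared across tests (seed fixed)."""
    return pipeline.run_pipeline(seed=1)


@pytest.fixture(scope="session")
def annotation(pipeline_result):
    return pipeline_result.ann


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_gene(
    gene_id="gA",
    chrom="chr1",
    strand="+",
    transcripts=((( 10, 50), (60, 100)),),
    coding=None,
):
    """Build a GeneModel from bare (start, end) tuples."""
    txs = [
        [GenomicInterval(chrom, s, e, strand) for s, e in tx] for tx in transcripts
    ]
    cds = (
        [[GenomicInterval(chrom, s, e, strand) for s, e in tx] for tx in coding]
        if coding is not None
        else [list(tx) for tx in txs]
    )
    lo = min(ex.start for tx in txs for ex in tx)
    hi = max(ex.end for tx in txs for ex in tx)
    return GeneModel(
        gene_id=gene_id,
        locus=GenomicInterval(chrom, lo, hi, strand),
        transcripts=txs,
        coding_spans=cds,
    )
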