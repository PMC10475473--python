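import pytest

from txcoloc.annotation import (
    GenomicInterval,
    TranscriptIndex,
    TranscriptModel,
)
from txcoloc.synthetic import SynthAnnotSpec, generate_annotation, generate_rois


def make_tx(tx_id="t1", gene_id="g1", chrom="chr1", strand="+",
            exons=((100, 200), (300, 400)), cds=(150, 350)):
    return TranscriptModel(
        tx_id, gene_id, chrom, strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        cds,
    )


@pytest.fixture
def tx_plus():
    """Two-exon plus-strand transcript: exons (100,200),(300,400), CDS (150,350)."""
    return make_tx()


@pytest.fixture
def tx_minus():
    return make_tx(tx_id="t1m", strand="-")


@pytest.fixture
def shared_pair_index():
    """Two isoforms sharing exon [100,200); t2 has a private exon [500,600)."""
    t1 = make_tx(tx_id="t1", exons=((100, 200), (300, 400)), cds=None)
    t2 = make_tx(tx_id="t2", exons=((100, 200), (500, 600)), cds=None)
    return TranscriptIndex([t1, t2])


@pytest.fixture(scope="session")
def synth_index():
    """Session-wide synthetic transcriptome: 30 genes x 3 isoforms, shared exons."""
    txs = generate_annotation(SynthAnnotSpec(seed=11))
    return TranscriptIndex(txs)


@pytest.fixture(scope="session")
def synth_rois(synth_index):
    return generate_rois(synth_index)
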