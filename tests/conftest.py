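import numpy as np
import pytest

from epimn.genome import GenomicInterval, TranscriptModel


@pytest.fixture
def single_exon_model():
    """Plus-strand, single exon [0, 300) with CDS [100, 250)."""
    return TranscriptModel(
        transcript_id="tx1",
        gene_id="geneA",
        exons=[GenomicInterval("chr1", 0, 300, "+")],
        utr5_len=100,
        cds_len=150,
        utr3_len=50,
    )


@pytest.fixture
def minus_strand_model():
    """Two-exon minus-strand transcript: exons [500,600) then [100,400)
    in genomic order; 5'->3' order is the reverse."""
    return TranscriptModel(
        transcript_id="tx2",
        gene_id="geneB",
        exons=[
            GenomicInterval("chr1", 500, 600, "-"),
            GenomicInterval("chr1", 100, 400, "-"),
        ],
        utr5_len=50,
        cds_len=300,
        utr3_len=50,
    )


def random_models(n: int, seed: int = 0) -> list[TranscriptModel]:
    """Multi-exon transcripts on both strands with valid partitions."""
    rng = np.random.default_rng(seed)
    models = []
    cursor = 0
    for i in range(n):
        n_exons = int(rng.integers(1, 5))
        strand = "+" if rng.random() < 0.5 else "-"
        exons_fwd = []
        pos = cursor + int(rng.integers(100, 500))
        for _ in range(n_exons):
            length = int(rng.integers(50, 400))
            exons_fwd.append(GenomicInterval("chrR", pos, pos + length, strand))
            pos += length + int(rng.integers(30, 200))
        cursor = pos + 1000
        total = sum(len(e) for e in exons_fwd)
        utr5 = int(rng.integers(0, total // 3))
        utr3 = int(rng.integers(0, total // 3))
        cds = total - utr5 - utr3
        exons = exons_fwd if strand == "+" else list(reversed(exons_fwd))
        models.append(
            TranscriptModel(f"rtx{i}", f"rg{i}", exons, utr5, cds, utr3)
        )
    return models
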