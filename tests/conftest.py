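import numpy as np
import pytest

from exprss.gene_models import GeneModel, TranscriptModel, build_index


def make_gene(gene_id, chrom, strand, start, end, tx_ends=None, biotype="protein_coding"):
    """Single-exon gene; tx_ends optionally lists alternative 3' ends."""
    if tx_ends is None:
        transcripts = [TranscriptModel(f"{gene_id}.1", strand, ((start, end),))]
    else:
        transcripts = []
        for k, e3 in enumerate(tx_ends, start=1):
            exons = ((start, e3),) if strand == "+" else ((e3, end),)
            transcripts.append(TranscriptModel(f"{gene_id}.{k}", strand, exons))
    return GeneModel(gene_id, chrom, strand, start, end, tuple(transcripts), biotype)


@pytest.fixture
def toy_index():
    """Hand-laid annotation exercising each assignment rule.

    chr1 (+ unless noted):
      geneA [1000, 2000)           plain sense gene
      geneB [3000, 4000)           upstream neighbour; window [4000, 4500)
      geneC [4200, 5200) on -      antisense gene overlapping geneB's window
      geneD [6000, 7000) and geneE [6800, 7600)  overlapping gene limits
      geneF [9000, 9800) on -      isolated minus-strand gene
    """
    genes = [
        make_gene("geneA", "chr1", "+", 1000, 2000),
        make_gene("geneB", "chr1", "+", 3000, 4000),
        make_gene("geneC", "chr1", "-", 4200, 5200),
        make_gene("geneD", "chr1", "+", 6000, 7000),
        make_gene("geneE", "chr1", "+", 6800, 7600),
        make_gene("geneF", "chr1", "-", 9000, 9800),
    ]
    return build_index(genes, window_bp=500)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
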