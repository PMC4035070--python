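"""Simulate a barcoded tag library and recover its counts exactly.

Builds a synthetic 40-gene transcriptome, simulates an error-free 20,000-read
library with a 4-nt barcode, then runs the full downstream pipeline:
demultiplex -> exact read placement -> tag-to-gene assignment -> count
matrix, and compares against the simulator's ground truth.
"""

from exprss import (
    BarcodeSet,
    align_reads_exact,
    assign_read,
    build_count_matrix,
    demultiplex,
    make_transcriptome,
    simulate_library,
)

transcriptome = make_transcriptome(n_genes=40, paralog_fraction=0.0,
                                   antisense_fraction=0.0, seed=1)
library = simulate_library(transcriptome, n_reads=20_000, barcode="TAGC",
                           seed=2, sample_id="rep1")

demux = demultiplex(library.reads1, BarcodeSet([("rep1", "TAGC")]))
print(f"demultiplexed: {demux.summary}")

tags, unaligned = align_reads_exact(demux.by_sample["rep1"],
                                    transcriptome.chrom_sequences)
assignments = [assign_read(t, transcriptome.index) for t in tags]
matrix = build_count_matrix({"rep1": assignments})
print(matrix)

recovered = matrix.layer("sense")["rep1"]
exact = sum(
    abs(recovered.get(g, 0.0) - c) < 1e-9
    for (g, _), c in library.truth.counts.items()
)
print(f"genes recovered exactly: {exact}/{len(library.truth.counts)}")
# With no sequencing errors and unique 3' sequences every gene's count
# matches the simulator's truth — the pipeline neither loses nor invents tags.
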