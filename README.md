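# exprss

Downstream analysis for **randomly-sheared 3′ cDNA tag sequencing**
(Tag-seq).  In these protocols each transcript yields exactly one short
sequencing tag near its polyadenylation site: double-stranded cDNA primed
with an anchored oligo-dT primer is acoustically sheared to ~200 bp, and a
Y-shaped adapter restricts amplification to the 3′-most fragment.  Relative
gene expression is then simply the tag count — no transcript-length
normalization — and the strandedness and 3′ anchoring of the tags expose
alternative polyadenylation (APA), polyadenylated antisense transcripts and
unannotated transcription.

The package is aimed at people analysing such libraries (or building
variants of the protocol) and covers everything downstream of base calling
and short-read alignment:

- **Demultiplexing** of variable-length (3–6 nt) barcodes by exact prefix
  match, or ≤1-mismatch matching for the restriction-anchored (NlaIII-DGE)
  dialect, plus barcode-pool base-balance QC.
- **Filtering**: FASTX-style quality filter (≥ *p*% of bases at phred ≥ *q*,
  defaults 50%/Q20, N-containing reads discarded), near-homopolymer
  artifact removal, NlaIII adapter clipping with CATG restoration.
- **Tag-to-gene assignment** over two-pass (genome, then transcript)
  alignments: sense tags within gene limits, equal splitting of reads
  matching up to 10 genes (more are discarded), rescue of apparently
  antisense tags that fall within 500 bp downstream of another gene's 3′
  end in sense orientation, antisense counting otherwise.  Counts are
  fractional and conserve read mass exactly.
- **3′ profiling**: distance-from-3′-end histograms, a poly(A)-site peak
  caller with a 200 bp separation limit (sites closer than that are not
  resolvable from sheared tags), antisense peak localization, novel-region
  detection from unassigned reads, and poly(A)-site verification from
  paired-end read 2 (which starts at the poly(A) junction).
- **Expression**: tags-per-million (TPM) normalization, the ≥1 TPM over ≥4
  replicates detection filter, log2 fold changes, replicate correlation of
  log10(TPM+1), and an integer-count export for external
  negative-binomial differential-expression tools.
- **Simulation**: a sheared-cDNA library simulator with full ground truth
  (paralog families, APA isoforms, antisense transcripts, rRNA decoys), so
  every stage is testable without external data.

## The model in brief

A cDNA fragment of length *F* ~ TruncNormal(μ=200, σ=30; [100, 350]) bp
carries *P* = 48 bp of primer, so the tag starts

&nbsp;&nbsp;&nbsp;&nbsp;*D* = max(1, *F* − *P*) bp

upstream of the poly(A) site.  Under the defaults ~90%+ of tags fall within
300 bp of the 3′ end with the modal 10-bp bin at 150 bp — the signature of
random shearing, and the yardstick the distance profiler applies to real
libraries.  TPM for gene *g* in sample *s* is
`count(g,s) / total_assigned(s) × 1e6`, with sense and antisense layers
sharing one denominator.

## Worked example

```bash
python examples/02_end_to_end_pipeline.py
```

```
demultiplexed: {'sample:rep1': 20000, 'no_distinct_barcode': 0, 'total': 20000}
CountMatrix(38 genes x 1 samples, 20000 assigned reads)
genes recovered exactly: 38/38
```

All 20,000 simulated reads carry the expected barcode, every read is
assigned, and — with no sequencing errors and unique 3′ sequences — every
gene's recovered count equals the simulator's ground truth.  The other
examples cover the shearing model (`01`), APA calling and its 200 bp
resolution limit (`03`), technical-replicate correlation (`04`), and
antisense/novel-region detection (`05`).

A thin CLI wraps the same functions for shell pipelines:

```bash
exprss simulate --n-genes 60 --n-reads 100000 --barcode ACGT --seed 1 --out-dir sim/
exprss demux    --fastq sim/reads_1.fastq --sample-sheet samples.tsv --out-dir demux/
exprss filter   --fastq demux/s1.fastq -q 20 -p 50 --out s1.filtered.fastq
exprss assign   --genome-sam s1.genome.sam --transcript-sam s1.tx.sam \
                --gff annotation.gff3 --out counts.tsv
exprss counts   --counts counts.tsv --tpm-out tpm.tsv --detect-out detected.tsv
```

Alignment itself (bowtie/BWA) is consumed as SAM, not re-implemented; an
exact-match placer for error-free synthetic reads is included for
self-contained testing.

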