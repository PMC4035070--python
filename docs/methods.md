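# Methods

## The measurement model

Randomly-sheared 3′ tag sequencing produces one read per cDNA molecule,
anchored at its 3′ end.  An anchored oligo-dT primer (terminated V·N, where
V = A/C/G, so that synthesis starts exactly at the poly(A) junction; 12
concrete primer species, redesigned as 9 phosphorothioate V*B + 3 VA species
to suppress oligo-dT ligation artifacts) initiates first-strand synthesis;
double-stranded cDNA is acoustically sheared to a target of ~200 bp; a
Y-shaped adapter restricts amplification to the 3′-most fragment.  The
sequenced tag therefore starts where shearing happened to cut, a
fragment-length-minus-primer distance upstream of the poly(A) site.

We model the fragment length as Normal(μ, σ) truncated to the gel
size-selection window, with defaults

| parameter      | default   | meaning                                     |
|----------------|-----------|---------------------------------------------|
| `fragment_mean`| 200 bp    | acoustic shearing target size               |
| `fragment_sd`  | 30 bp     | shear width (calibration choice)            |
| `size_selection`| [100, 350] bp | gel window retained for sequencing     |
| `primer_len`   | 48 bp     | oligo-dT/flow-cell primer within fragments  |

The tag-start distance is `max(1, round(F) − 48)`.  Only the 200 bp target
and 48 bp primer are protocol constants; σ and the window are calibration
choices that reproduce the expected distance profile (~90%+ of tags within
300 bp, modal 10-bp bin at 150 bp; the analytic mode of the truncated
Normal(200, 30) minus 48 is 152, which falls in the [150, 160) bin).  The
true post-gel fragment distribution is not published for any instrument
setting, so all four parameters remain user-tunable.

## Read processing

Quality filtering follows FASTX `-q`/`-p` semantics: a read passes when at
least *p*% of bases (default 50, boundary inclusive — 18 of 36 bases
passes) reach phred *q* (default 20) and it contains no N.  Phred-offset
auto-detection scans up to 10,000 reads: any quality character below `@`
implies phred+33; all characters at or above `B` imply phred+64; anything
else raises and requires an explicit offset.  Note a file whose qualities
are uniformly high (all ≥ `B`) is classified phred+64 even if it was
written as phred+33 — constant-quality files are genuinely ambiguous, and
the library's own simulator writes Q30 (`?`) so its output self-identifies
as phred+33.

The artifact filter removes reads where all but at most 3 bases are copies
of the most frequent base.  This is a documented reconstruction of the
FASTX 0.0.13 artifact filter (whose exact rule is not published); it
catches the poly(A)/poly(T) near-homopolymers produced by oligo-dT/adapter
ligation.

Demultiplexing: barcodes are 3–6 nt and of deliberately varying length so
an equimolar pool keeps each sequencing cycle near 25% per base
(`barcode_balance` reports the per-cycle deviation, padding beyond a
barcode's length with a uniform placeholder since the insert behind it is
effectively random).  Exact-prefix matching requires a prefix-free barcode
set, which is checked before any read is processed; matching is then
order-independent.  The NlaIII dialect allows one mismatch but requires the
≤1-mismatch hit to be unique — a read within distance 1 of two barcodes is
unassigned even if one match is exact.  This is the conservative reading of
"up to 1 mismatch"; mismatches are counted over the barcode length only.
NlaIII adapter clipping searches for the full adapter first, then for an
adapter prefix (≥5 nt) anchored at the read's 3′ end; clipped tags shorter
than 18 nt and reads without adapter are discarded, and survivors get the
anchoring-enzyme site CATG restored at the 5′ end with constant quality 37
(`FFFF`).

## Tag-to-gene assignment

Alignments are consumed, never produced: a genome pass (reads with up to 10
reportable alignments) and a transcript pass over the reads the genome pass
could not place (exon-junction tags).  A read mapped in both passes
violates this contract and raises.  Per alignment:

1. same-strand overlap with a gene's limits → sense candidate.  "Gene
   limits" are the full annotated span including introns and UTRs: 3′ tags
   rarely hit introns, and junction reads are caught by the transcript
   pass, so the simpler rule is adequate and much cheaper.
2. overlap with several genes → all become candidates.
3. antisense overlap → if the read's 5′-most base lies within the 500-bp
   window past another gene's 3′ end *on the read's strand*, that gene
   gains a **sense** candidate (the tag extends an unannotated 3′ UTR);
   otherwise the overlapped gene gains an antisense candidate.  Sense
   containment is evaluated before window rescue per alignment.

Transcript-pass alignments map to the parent gene; multiple splice variants
of one gene collapse to a single candidate before the gene cap is applied.
Candidates are deduplicated per (gene, orientation) across alignments.
Reads resolving to more than 10 genes are discarded; otherwise the read's
unit weight splits equally over candidates — a single joint split even when
paralogy and overlapping limits co-occur.  Reads with no candidates remain
unassigned and feed novel-region detection.  Weight conservation (Σ weights
= 1 per assigned read, matrix mass = assigned reads per sample) is
asserted in tests against an independent linear-scan re-implementation of
the rule list.

Coordinates are 0-based half-open internally, 1-based in GFF3 output.  The
longest splice variant (by summed exon length, ties broken by transcript
id) defines a gene's reference 3′ end for distance profiling.  The 500-bp
window is measured in genomic bp past the 3′ end regardless of neighbouring
annotation — truncating it at the next gene would only matter for
unusually dense annotations and would make the rule order-dependent.

## Peak calling

No peak-calling algorithm is prescribed by the protocol, only the
constraint that poly(A) sites closer than 200 bp are not resolvable from
sheared tags.  The caller therefore: bins positions at 25 bp (edges at
multiples of 25), smooths with a centred 3-bin moving average, collects
local maxima (plateau bins all qualify; the greedy separation step then
keeps one), filters candidates by window support (≥5 tags and ≥10% of the
gene's tags within the smoothing window), and accepts candidates greedily
by descending smoothed height rejecting anything within 200 bp of an
accepted call.  Every tag is finally attributed to its nearest accepted
call, so call fractions estimate isoform usage rather than just local bin
mass.  Calls are ordered 3′-most first; the 3′-most is `primary`.  The same
machinery drives antisense peaks (highest surviving call) and read-2
poly(A) calls.

Read 2 of a pair starts at the poly(A) junction and aligns antisense to the
transcript; its 5′-most genomic base is taken as the poly(A) position
(upstream poly(A)-tail trimming is assumed done before alignment).  Calls
within 50 bp of an annotated transcript 3′ end are flagged annotated,
others novel.

Novel regions merge unassigned alignments per strand with a 100 bp gap
tolerance and require ≥10 supporting reads — a depth chosen because single
desk-scale libraries rarely support such regions; pooling samples first is
expected.

## Expression

TPM = count / total assigned tags × 1e6, both orientation layers sharing
one denominator because they come from one sequencing pool.  The detection
filter defaults to "mean TPM over ≥4 replicates ≥ 1"; the statement is
ambiguous between mean-over-replicates and each-replicate thresholds, so
`mode="each"` provides the stricter reading.  Fold changes use
log2((mean+1)/(mean+1)) with a configurable 1-TPM pseudocount.  Replicate
QC is Pearson correlation of log10(TPM+1).  Differential-expression testing
is deliberately not reimplemented; `export_for_de` writes rounded integer
counts plus a design table for external negative-binomial tools.

## What the simulator does and does not emulate

`make_transcriptome` generates single-exon genes (mean length 1.5 kb, sd
400, min 400 bp) on one chromosome with 600 bp intergenic gaps and random
strands; ~10% of genes form paralog pairs sharing their 3′-most 300 bp,
~10% carry a second poly(A) site 500 bp upstream used by 30% of transcripts,
~17% an antisense transcript with a defined poly(A) site 150 bp inside the
gene, ~10% a second splice variant ending 200 bp upstream, plus two
rRNA-biotype decoys.  `simulate_library` draws (gene, orientation) ∝
expression, isoform ∝ usage, fragment from the shearing model, and emits
barcoded 36-nt reads (configurable up to 150) at constant Q30 with optional
uniform substitution errors and optional poly(A)-junction read 2.  All
draws are recorded as ground truth; everything is deterministic per seed.

Not emulated: multi-exon structure in generated genes (splice-variant
handling is exercised through annotation, not junction reads), PCR/GC bias,
indels, quality-score decay along the read, chimeras, and the NlaIII
library chemistry (the NlaIII dialect is tested on hand-built reads).
Passing tests on these simulations therefore demonstrate correctness of
the downstream bookkeeping under the stated generative model — exact truth
recovery, invariance properties, resolution limits — not robustness to
every artifact of real sequencing data.  The included exact-match read
placer exists so error-free synthetic reads can flow through assignment
without an external aligner; real libraries go through bowtie/BWA and SAM.

## Problem sizes

Tests and examples run at desk scale: transcriptomes of 15–200 genes and
libraries of 400–100,000 reads.  End-to-end truth recovery and the
replicate-correlation property use 1e5 reads; peak-calling properties use
500 tags per gene, matching the planted-usage binomial error analysis
(3 standard deviations at n = 500 is ±6.1 usage points).
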