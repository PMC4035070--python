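"""Synthetic transcriptomes and sheared-cDNA tag libraries with ground truth.

The simulator emulates the statistical structure of a randomly-sheared 3'
tag library: double-stranded cDNA sheared to ~200 bp fragments, of which
48 bp is the oligo-dT/flow-cell primer, leaves tags starting ~150 bp (give or
take the shear width) upstream of the poly(A) site.  Fragment lengths follow
a truncated Normal within the gel size-selection window; the tag-start
distance is the fragment length minus the primer, floored at 1.

Synthetic transcriptomes carry the annotation features that exercise the
assignment rules: paralog families with identical 3'-most 300 bp (forcing
multi-mapping), genes with a second poly(A) site well upstream (alternative
polyadenylation), antisense transcripts with defined poly(A) sites, splice
variants with distinct 3' ends, and rRNA-like decoy loci.  Every simulated
read's provenance is recorded so recovered counts can be compared with truth
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .gene_models import AnnotationIndex, GeneModel, TranscriptModel, build_index
from .read_processing import RawRead
from .tag_assignment import AlignedTag, Alignment

__all__ = [
    "ShearingModel",
    "ApaIsoform",
    "AntisenseTranscript",
    "SyntheticTranscriptome",
    "SyntheticTruth",
    "SimulatedLibrary",
    "make_transcriptome",
    "simulate_library",
    "sample_fragment_distances",
    "align_reads_exact",
    "write_sam",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ShearingModel:
    """Fragment-size and size-selection parameters of acoustic cDNA shearing.

    ``fragment_mean``/``fragment_sd`` parameterize the (truncated) Normal
    fragment-length distribution in bp; ``size_selection`` is the gel window
    retained for sequencing; ``primer_len`` is the oligo-dT/flow-cell primer
    contribution to each fragment, so the transcript-derived part of a
    fragment — the tag-start distance from the poly(A) site — is the fragment
    length minus ``primer_len``.
    """

    fragment_mean: float = 200.0
    fragment_sd: float = 30.0
    primer_len: int = 48
    size_selection: tuple[float, float] = (100.0, 350.0)

    def __post_init__(self) -> None:
        low, high = self.size_selection
        if not low < high:
            raise ValueError("size_selection low must be < high")
        if self.fragment_sd <= 0 and not low <= self.fragment_mean <= high:
            raise ValueError("degenerate fragment distribution outside selection window")

    def draw_fragments(self, n: int, rng: np.random.Generator) -> np.ndarray:
        low, high = self.size_selection
        if self.fragment_sd <= 0:
            return np.full(n, self.fragment_mean)
        a = (low - self.fragment_mean) / self.fragment_sd
        b = (high - self.fragment_mean) / self.fragment_sd
        return truncnorm.rvs(
            a, b, loc=self.fragment_mean, scale=self.fragment_sd, size=n,
            random_state=rng,
        )


def sample_fragment_distances(
    model: ShearingModel,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Draw tag-start distances implied by the shearing model.

    Distances are rounded fragment lengths minus the primer length, floored
    at 1 bp.  The summary reports the fraction of distances within 300 bp of
    the 3' end and the left edge of the most populated 10-bp bin; under the
    default model ~90%+ of tags fall within 300 bp with the peak near 150 bp.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    fragments = np.round(model.draw_fragments(n, rng)).astype(int)
    distances = np.maximum(1, fragments - model.primer_len)
    bins = (distances // 10) * 10
    left_edges, counts = np.unique(bins, return_counts=True)
    summary = {
        "fraction_within_300": float((distances <= 300).mean()),
        "modal_bin_left": int(left_edges[int(np.argmax(counts))]),
        "n": int(n),
    }
    return distances, summary


@dataclass(frozen=True)
class ApaIsoform:
    """One polyadenylation isoform: 3' end in transcript coords, usage, genomic site."""

    tx_length: int
    usage: float
    genomic_site: int


@dataclass(frozen=True)
class AntisenseTranscript:
    """An (unannotated) polyadenylated antisense transcript of a gene."""

    sequence: str
    genomic_site: int  # poly(A) site: genomic position of the 3'-most base
    strand: str


@dataclass
class SyntheticTranscriptome:
    """Synthetic genome + annotation + per-gene isoform/antisense truth."""

    chrom_sequences: dict[str, str]
    genes: list[GeneModel]
    index: AnnotationIndex
    transcript_seqs: dict[str, str]
    apa: dict[str, list[ApaIsoform]]
    antisense: dict[str, AntisenseTranscript]
    paralog_families: list[tuple[str, ...]]
    rrna_gene_ids: list[str]

    def write_genome_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.chrom_sequences):
                fh.write(f">{chrom}\n")
                seq = self.chrom_sequences[chrom]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_transcripts_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tid in sorted(self.transcript_seqs):
                fh.write(f">{tid}\n")
                seq = self.transcript_seqs[tid]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                fh.write(
                    f"{gene.chrom}\tsim\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                    f"{gene.strand}\t.\tID={gene.gene_id};biotype={gene.biotype}\n"
                )
                for tx in gene.transcripts:
                    fh.write(
                        f"{gene.chrom}\tsim\tmRNA\t{tx.start + 1}\t{tx.end}\t.\t"
                        f"{gene.strand}\t.\tID={tx.transcript_id};Parent={gene.gene_id}\n"
                    )
                    for k, (es, ee) in enumerate(tx.exons, start=1):
                        fh.write(
                            f"{gene.chrom}\tsim\texon\t{es + 1}\t{ee}\t.\t"
                            f"{gene.strand}\t.\tID={tx.transcript_id}.exon{k};"
                            f"Parent={tx.transcript_id}\n"
                        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def make_transcriptome(
    n_genes: int = 60,
    length_mean: float = 1500.0,
    length_sd: float = 400.0,
    min_length: int = 400,
    paralog_fraction: float = 0.1,
    apa_fraction: float = 0.1,
    antisense_fraction: float = 0.17,
    variant_fraction: float = 0.1,
    n_rrna: int = 2,
    apa_offset: int = 500,
    apa_usage: tuple[float, float] = (0.7, 0.3),
    intergenic_gap: int = 600,
    seed: int = 0,
    window_bp: int = 500,
) -> SyntheticTranscriptome:
    """Generate a synthetic single-exon transcriptome on one chromosome.

    Defaults emulate the structure of a plant transcriptome as seen by 3'
    tag sequencing: ~1.5 kb mean transcript length, ~10% of genes in paralog
    pairs sharing their 3'-most 300 bp, ~10% with an alternative poly(A) site
    500 bp upstream used by 30% of transcripts, ~17% carrying a polyadenylated
    antisense transcript, plus rRNA-like decoy loci.  Deterministic for a
    fixed seed.
    """
    for name, frac in (
        ("paralog_fraction", paralog_fraction),
        ("apa_fraction", apa_fraction),
        ("antisense_fraction", antisense_fraction),
        ("variant_fraction", variant_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_genes < 2 and paralog_fraction > 0:
        raise ValueError("paralog families need at least 2 genes")
    if abs(sum(apa_usage) - 1.0) > 1e-9:
        raise ValueError("apa_usage must sum to 1")

    rng = np.random.default_rng(seed)
    lengths = np.clip(
        np.round(rng.normal(length_mean, length_sd, n_genes)).astype(int),
        min_length,
        None,
    )

    order = rng.permutation(n_genes)
    n_pairs = int(round(paralog_fraction * n_genes / 2))
    n_apa = int(round(apa_fraction * n_genes))
    n_anti = int(round(antisense_fraction * n_genes))
    n_var = int(round(variant_fraction * n_genes))
    pair_idx = [
        (order[i], order[i + 1]) for i in range(0, 2 * n_pairs, 2)
    ]
    cursor = 2 * n_pairs
    apa_idx = set(order[cursor : cursor + n_apa]); cursor += n_apa
    anti_idx = set(order[cursor : cursor + n_anti]); cursor += n_anti
    var_idx = set(order[cursor : cursor + n_var]); cursor += n_var
    rrna_idx = set(order[cursor : cursor + n_rrna])

    # APA genes must accommodate the upstream site plus a tag's worth of sequence
    for i in apa_idx:
        lengths[i] = max(lengths[i], apa_offset + min_length)

    tx_seqs: dict[int, str] = {
        i: _random_seq(rng, int(lengths[i])) for i in range(n_genes)
    }
    for a, b in pair_idx:
        # paralogs share their 3'-most 300 nt -> multi-mapping tags
        tx_seqs[b] = tx_seqs[b][:-300] + tx_seqs[a][-300:]

    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")

    chrom = "chr1"
    genome_parts: list[str] = []
    genes: list[GeneModel] = []
    transcript_seqs: dict[str, str] = {}
    apa: dict[str, list[ApaIsoform]] = {}
    antisense: dict[str, AntisenseTranscript] = {}
    rrna_ids: list[str] = []
    pos = 0
    for i in range(n_genes):
        gap = _random_seq(rng, intergenic_gap)
        genome_parts.append(gap)
        pos += intergenic_gap
        gene_id = f"SYN{i + 1:04d}"
        seq = tx_seqs[i]
        strand = str(strands[i])
        start, end = pos, pos + len(seq)
        genome_parts.append(seq if strand == "+" else revcomp(seq))
        pos = end

        full_id = f"{gene_id}.1"
        transcripts = [
            TranscriptModel(full_id, strand, ((start, end),))
        ]
        transcript_seqs[full_id] = seq
        if i in var_idx and len(seq) > 200 + min_length:
            short_id = f"{gene_id}.2"
            exons = (
                ((start, end - 200),) if strand == "+" else ((start + 200, end),)
            )
            transcripts.append(TranscriptModel(short_id, strand, exons))
            transcript_seqs[short_id] = seq[:-200]
        biotype = "rRNA" if i in rrna_idx else "protein_coding"
        gene = GeneModel(gene_id, chrom, strand, start, end, tuple(transcripts), biotype)
        genes.append(gene)
        if biotype == "rRNA":
            rrna_ids.append(gene_id)

        L = len(seq)
        site_full = end if strand == "+" else start
        if i in apa_idx:
            site_up = end - apa_offset if strand == "+" else start + apa_offset
            apa[gene_id] = [
                ApaIsoform(L, apa_usage[0], site_full),
                ApaIsoform(L - apa_offset, apa_usage[1], site_up),
            ]
        else:
            apa[gene_id] = [ApaIsoform(L, 1.0, site_full)]

        if i in anti_idx:
            as_len = min(800, L - 150)
            if strand == "+":
                # '-' strand transcript covering [p, p + as_len); 3' end at p
                p = start + 150
                as_seq = revcomp(seq[150 : 150 + as_len])
                antisense[gene_id] = AntisenseTranscript(as_seq, p, "-")
            else:
                # '+' strand transcript covering [p - as_len, p); 3' end at p
                p = end - 150
                offset = (p - as_len) - start
                as_seq = revcomp(seq)[offset : offset + as_len]
                antisense[gene_id] = AntisenseTranscript(as_seq, p, "+")

    chrom_sequences = {chrom: "".join(genome_parts)}
    index = build_index(genes, window_bp=window_bp, rrna_gene_ids=rrna_ids)
    return SyntheticTranscriptome(
        chrom_sequences=chrom_sequences,
        genes=genes,
        index=index,
        transcript_seqs=transcript_seqs,
        apa=apa,
        antisense=antisense,
        paralog_families=[(f"SYN{a + 1:04d}", f"SYN{b + 1:04d}") for a, b in pair_idx],
        rrna_gene_ids=rrna_ids,
    )


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated library."""

    counts: dict[tuple[str, str], int]  # (gene_id, orientation) -> reads
    site_counts: dict[tuple[str, int], int]  # (gene_id, genomic poly(A) site) -> reads
    distances: np.ndarray  # per-read tag-start distance from the poly(A) site

    @property
    def n_reads(self) -> int:
        return int(sum(self.counts.values()))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\torientation\tcount\n")
            for (gene_id, orientation), count in sorted(self.counts.items()):
                fh.write(f"{gene_id}\t{orientation}\t{count}\n")


@dataclass
class SimulatedLibrary:
    """Simulated reads plus their ground truth."""

    sample_id: str
    barcode: str
    reads1: list[RawRead]
    reads2: list[RawRead] | None
    truth: SyntheticTruth


def simulate_library(
    transcriptome: SyntheticTranscriptome,
    expression_levels: Mapping[str, float] | None = None,
    shearing: ShearingModel | None = None,
    n_reads: int = 10_000,
    barcode: str = "",
    error_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 36,
    paired: bool = False,
    antisense_levels: Mapping[str, float] | None = None,
    sample_id: str = "sim",
) -> SimulatedLibrary:
    """Simulate one barcoded sheared-cDNA tag library.

    Each read draws a (gene, orientation) proportional to the expression
    levels, a poly(A) isoform proportional to its usage, and a fragment from
    the shearing model; read 1 runs from the tag start toward the 3' end
    (truncated at ``read_length``), gets the barcode prepended and optional
    uniform substitution errors.  With ``paired=True`` read 2 is anchored at
    the poly(A) junction (reverse complement of the isoform's 3' terminus).
    Deterministic for fixed inputs and seed.
    """
    if shearing is None:
        shearing = ShearingModel()
    if expression_levels is None:
        expression_levels = {
            g.gene_id: 1.0
            for g in transcriptome.genes
            if g.biotype != "rRNA"
        }
    rng = np.random.default_rng(seed)

    units: list[tuple[str, str]] = []
    weights: list[float] = []
    for gene_id, level in expression_levels.items():
        if level < 0:
            raise ValueError(f"negative expression level for {gene_id}")
        if level > 0:
            units.append((gene_id, "sense"))
            weights.append(float(level))
    if antisense_levels:
        for gene_id, level in antisense_levels.items():
            if gene_id not in transcriptome.antisense:
                raise ValueError(f"gene {gene_id} has no antisense transcript")
            if level > 0:
                units.append((gene_id, "antisense"))
                weights.append(float(level))
    if not units:
        raise ValueError("all expression levels are zero")
    probs = np.asarray(weights) / np.sum(weights)

    choices = rng.choice(len(units), size=n_reads, p=probs)
    fragments = np.round(shearing.draw_fragments(n_reads, rng)).astype(int)
    distances = np.maximum(1, fragments - shearing.primer_len)
    iso_draws = rng.random(n_reads)
    error_draws = rng.random(n_reads) if error_rate > 0 else None

    counts: dict[tuple[str, str], int] = {}
    site_counts: dict[tuple[str, int], int] = {}
    reads1: list[RawRead] = []
    reads2: list[RawRead] | None = [] if paired else None
    for i in range(n_reads):
        gene_id, orientation = units[choices[i]]
        if orientation == "sense":
            isoforms = transcriptome.apa[gene_id]
            u, acc = iso_draws[i], 0.0
            iso = isoforms[-1]
            for cand in isoforms:
                acc += cand.usage
                if u < acc:
                    iso = cand
                    break
            tx = transcriptome.transcript_seqs[f"{gene_id}.1"][: iso.tx_length]
            site = iso.genomic_site
        else:
            anti = transcriptome.antisense[gene_id]
            tx = anti.sequence
            site = anti.genomic_site
        d = int(distances[i])
        tag_start = max(0, len(tx) - d)
        seq = tx[tag_start : min(len(tx), tag_start + read_length)]
        if error_rate > 0:
            seq = _apply_errors(seq, error_rate, rng)
        read_id = f"{sample_id}:{i:07d}"
        reads1.append(RawRead(read_id, barcode + seq, [30] * (len(barcode) + len(seq))))
        if paired:
            tail = tx[max(0, len(tx) - read_length) :]
            r2 = revcomp(tail)
            if error_rate > 0:
                r2 = _apply_errors(r2, error_rate, rng)
            reads2.append(RawRead(read_id, r2, [30] * len(r2)))
        counts[(gene_id, orientation)] = counts.get((gene_id, orientation), 0) + 1
        site_counts[(gene_id, site)] = site_counts.get((gene_id, site), 0) + 1

    truth = SyntheticTruth(counts, site_counts, distances)
    return SimulatedLibrary(sample_id, barcode, reads1, reads2, truth)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for j in np.nonzero(mask)[0]:
        alternatives = [b for b in "ACGT" if b != chars[j]]
        chars[j] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def align_reads_exact(
    reads: Iterable[RawRead],
    chrom_sequences: Mapping[str, str],
    seed_len: int | None = None,
) -> tuple[list[AlignedTag], list[str]]:
    """Place reads by exact full-length matching on both genome strands.

    A k-mer-seeded exact matcher for error-free synthetic libraries: every
    genomic position where the full read matches (forward, or reverse
    complement for the minus strand) becomes a reportable alignment, so
    paralog-derived multi-mapping emerges naturally.  Returns the aligned
    tags and the ids of reads with no match.
    """
    read_list = list(reads)
    if not read_list:
        return [], []
    k = seed_len or min(len(r.sequence) for r in read_list)
    if k < 1:
        raise ValueError("reads of zero length cannot be placed")
    kmer_index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in chrom_sequences.items():
        for pos in range(len(seq) - k + 1):
            kmer_index.setdefault(seq[pos : pos + k], []).append((chrom, pos))
    tags: list[AlignedTag] = []
    unaligned: list[str] = []
    for read in read_list:
        seq = read.sequence
        alignments: list[Alignment] = []
        for chrom, pos in kmer_index.get(seq[:k], ()):
            if chrom_sequences[chrom][pos : pos + len(seq)] == seq:
                alignments.append(Alignment(chrom, pos, pos + len(seq), "+", "genome"))
        rc = revcomp(seq)
        for chrom, pos in kmer_index.get(rc[:k], ()):
            if chrom_sequences[chrom][pos : pos + len(rc)] == rc:
                alignments.append(Alignment(chrom, pos, pos + len(rc), "-", "genome"))
        if alignments:
            tags.append(AlignedTag(read.read_id, alignments))
        else:
            unaligned.append(read.read_id)
    return tags, unaligned


def write_sam(
    tags: Iterable[AlignedTag],
    chrom_lengths: Mapping[str, int],
    path: str | Path,
    sequences: Mapping[str, str] | None = None,
) -> None:
    """Write aligned tags as a plain-text SAM file (ungapped alignments)."""
    import pysam

    refs = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r, "LN": int(chrom_lengths[r])} for r in refs],
    }
    ref_id = {r: i for i, r in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for tag in tags:
            for j, aln in enumerate(tag.alignments):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = tag.read_id
                rec.reference_id = ref_id[aln.ref]
                rec.reference_start = aln.start
                rec.mapping_quality = 255
                length = aln.end - aln.start
                rec.cigarstring = f"{length}M"
                rec.flag = (16 if aln.strand == "-" else 0) | (256 if j else 0)
                if sequences is not None and tag.read_id in sequences:
                    seq = sequences[tag.read_id]
                    rec.query_sequence = seq if aln.strand == "+" else revcomp(seq)
                out.write(rec)
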