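"""Tag-to-gene assignment over two-pass alignments.

Reads are first aligned to the genome; reads that fail to align (typically
exon-junction tags) are realigned to transcript sequences.  Each read's
reportable alignments are then pushed through a rule cascade:

1. a sense alignment within a gene's limits makes that gene a sense
   candidate; all splice variants of a gene collapse to one candidate;
2. an alignment inside overlapping genes makes every overlapping gene a
   candidate;
3. an antisense alignment is rescued as *sense* for a neighbouring gene when
   the read's 5'-most base falls within that gene's downstream window
   (default 500 bp past its 3' end, sense orientation) — these tags extend an
   unannotated 3' UTR; otherwise the overlapped gene gains an antisense
   candidate;
4. reads whose candidate set exceeds ``max_genes`` (default 10) are
   discarded; otherwise the read's unit weight is split equally across
   candidates;
5. reads with no candidates stay unassigned and feed novel-region detection.

Sense containment takes precedence over window rescue per alignment: rescue
applies only to alignments not sense-contained in any gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import pysam

from .gene_models import AnnotationIndex

__all__ = [
    "Alignment",
    "AlignedTag",
    "TagAssignment",
    "CountMatrix",
    "assign_read",
    "assign_library",
    "load_alignments",
    "build_count_matrix",
]

MAX_GENES_DEFAULT = 10


class Alignment(NamedTuple):
    """One reportable alignment of a read.

    ``ref`` is a chromosome for ``source == "genome"`` and a transcript id for
    ``source == "transcript"``; coordinates are 0-based half-open.
    """

    ref: str
    start: int
    end: int
    strand: str
    source: str = "genome"

    def five_prime(self) -> int:
        """Genomic position of the read's 5'-most aligned base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(slots=True)
class AlignedTag:
    """A read together with its set of reportable alignments (one pass only)."""

    read_id: str
    alignments: list[Alignment]

    @property
    def n_reportable(self) -> int:
        return len(self.alignments)


@dataclass(slots=True)
class TagAssignment:
    """Outcome of the rule cascade for one read.

    ``targets`` holds (gene_id, orientation, weight) triples; for an assigned
    read the weights are equal and sum to 1.  ``alignment`` keeps the first
    genomic alignment so distance profiling can locate unique tags.
    """

    read_id: str
    outcome: str  # assigned | discarded_multigene | unassigned
    targets: list[tuple[str, str, float]] = field(default_factory=list)
    alignment: Alignment | None = None


def assign_read(
    tag: AlignedTag, index: AnnotationIndex, max_genes: int = MAX_GENES_DEFAULT
) -> TagAssignment:
    """Apply the assignment rule cascade to one read's alignments."""
    candidates: dict[tuple[str, str], None] = {}  # insertion-ordered set
    representative: Alignment | None = None
    for aln in tag.alignments:
        if aln.source == "transcript":
            gene_id = index.transcript_to_gene.get(aln.ref)
            if gene_id is None:
                warnings.warn(
                    f"read {tag.read_id}: unknown transcript {aln.ref!r}",
                    stacklevel=2,
                )
                continue
            orientation = "sense" if aln.strand == "+" else "antisense"
            candidates.setdefault((gene_id, orientation))
            continue
        if aln.ref not in index.chroms:
            warnings.warn(
                f"read {tag.read_id}: unknown chromosome {aln.ref!r}", stacklevel=2
            )
            continue
        if representative is None:
            representative = aln
        hits = index.query_overlaps(aln.ref, aln.start, aln.end, aln.strand)
        if hits.sense:
            for gene in hits.sense:
                candidates.setdefault((gene.gene_id, "sense"))
        elif hits.antisense:
            rescued = index.downstream_window_genes(
                aln.ref, aln.five_prime(), aln.strand
            )
            if rescued:
                for gene in rescued:
                    candidates.setdefault((gene.gene_id, "sense"))
            else:
                for gene in hits.antisense:
                    candidates.setdefault((gene.gene_id, "antisense"))
        # alignment overlapping nothing contributes no candidate

    if not candidates:
        return TagAssignment(tag.read_id, "unassigned", alignment=representative)
    gene_set = {gene_id for gene_id, _ in candidates}
    if len(gene_set) > max_genes:
        return TagAssignment(tag.read_id, "discarded_multigene", alignment=representative)
    weight = 1.0 / len(candidates)
    targets = [(g, o, weight) for g, o in candidates]
    return TagAssignment(tag.read_id, "assigned", targets, representative)


def load_alignments(sam_path: str | Path, source: str) -> dict[str, AlignedTag]:
    """Group the mapped records of a SAM/BAM file into AlignedTags by read id."""
    tags: dict[str, AlignedTag] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            aln = Alignment(
                ref=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                source=source,
            )
            tag = tags.get(rec.query_name)
            if tag is None:
                tags[rec.query_name] = AlignedTag(rec.query_name, [aln])
            else:
                tag.alignments.append(aln)
    return tags


def assign_library(
    genome_sam: str | Path,
    transcript_sam: str | Path | None,
    index: AnnotationIndex,
    max_genes: int = MAX_GENES_DEFAULT,
) -> tuple[list[TagAssignment], dict[str, float]]:
    """Assign every read of a two-pass aligned library.

    ``transcript_sam`` holds the genome-unaligned reads realigned against
    transcript sequences; a read mapped in both passes violates the two-pass
    contract and raises.  Returns the per-read assignments and a summary with
    assignment-outcome fractions, sense/antisense weight split and the rRNA
    weight fraction.
    """
    genome_tags = load_alignments(genome_sam, "genome")
    transcript_tags = (
        load_alignments(transcript_sam, "transcript") if transcript_sam else {}
    )
    both = set(genome_tags) & set(transcript_tags)
    if both:
        raise ValueError(
            f"{len(both)} read(s) aligned in both passes (e.g. {sorted(both)[0]!r}); "
            "the transcript pass must contain only genome-unaligned reads"
        )
    assignments = [
        assign_read(tag, index, max_genes=max_genes)
        for tags in (genome_tags, transcript_tags)
        for tag in tags.values()
    ]
    return assignments, summarize_assignments(assignments, index)


def summarize_assignments(
    assignments: Sequence[TagAssignment], index: AnnotationIndex | None = None
) -> dict[str, float]:
    n = len(assignments)
    counts = {"assigned": 0, "discarded_multigene": 0, "unassigned": 0}
    sense_w = antisense_w = rrna_w = 0.0
    for a in assignments:
        counts[a.outcome] += 1
        for gene_id, orientation, weight in a.targets:
            if orientation == "sense":
                sense_w += weight
            else:
                antisense_w += weight
            if index is not None and gene_id in index.rrna_genes:
                rrna_w += weight
    summary: dict[str, float] = {"n_reads": float(n)}
    for key, val in counts.items():
        summary[f"n_{key}"] = float(val)
        summary[f"frac_{key}"] = val / n if n else 0.0
    total_w = sense_w + antisense_w
    summary["frac_sense"] = sense_w / total_w if total_w else 0.0
    summary["frac_antisense"] = antisense_w / total_w if total_w else 0.0
    summary["frac_rrna"] = rrna_w / total_w if total_w else 0.0
    return summary


class CountMatrix:
    """Gene x sample count matrix with separate sense/antisense layers.

    Values are fractional (multi-gene reads contribute equal fractions), and
    per sample the total mass over both layers equals the number of assigned
    reads — assignment conserves read weight.
    """

    def __init__(self, df: pd.DataFrame, totals: dict[str, float]):
        self.df = df
        self.totals = totals

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns.get_level_values(0).unique())

    def layer(self, orientation: str) -> pd.DataFrame:
        """Genes x samples values for one orientation layer."""
        return self.df.xs(orientation, axis=1, level=1)

    def to_tsv(self, path: str | Path, round_counts: bool = False) -> None:
        """Write ``gene_id<TAB>orientation<TAB>sample...`` TSV."""
        long = self.df.stack(level=1, future_stack=True).reset_index()
        long.columns = ["gene_id", "orientation", *self.samples]
        if round_counts:
            long[self.samples] = long[self.samples].round().astype(int)
        long.to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:
        return (
            f"CountMatrix({self.df.shape[0]} genes x {len(self.samples)} samples, "
            f"{sum(self.totals.values()):.0f} assigned reads)"
        )


def build_count_matrix(
    assignments_by_sample: Mapping[str, Iterable[TagAssignment]],
    gene_ids: Sequence[str] | None = None,
) -> CountMatrix:
    """Aggregate per-read assignments into a CountMatrix.

    ``gene_ids`` optionally fixes the gene axis (zero rows included);
    otherwise genes observed in the assignments are used.
    """
    values: dict[tuple[str, str], dict[str, float]] = {}
    totals: dict[str, float] = {}
    for sample, assignments in assignments_by_sample.items():
        n_assigned = 0
        for a in assignments:
            if a.outcome != "assigned":
                continue
            n_assigned += 1
            for gene_id, orientation, weight in a.targets:
                col = values.setdefault((sample, orientation), {})
                col[gene_id] = col.get(gene_id, 0.0) + weight
        totals[sample] = float(n_assigned)
        for orientation in ("sense", "antisense"):
            values.setdefault((sample, orientation), {})
    df = pd.DataFrame(values).fillna(0.0)
    if gene_ids is not None:
        df = df.reindex(list(gene_ids), fill_value=0.0)
    df = df.sort_index()
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["sample", "orientation"])
    df = df.sort_index(axis=1)
    return CountMatrix(df, totals)
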