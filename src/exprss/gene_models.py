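"""Gene annotation models and strand-aware 3'-end geometry.

Tag-seq reads cluster near transcript 3' ends, so everything downstream of
alignment — assignment, distance profiles, polyadenylation calls — is phrased
in terms of a gene's 3' end and the window just past it.  This module loads a
GFF3/GTF annotation into an :class:`AnnotationIndex` that answers the three
queries the rest of the package needs:

* which genes does an interval overlap, on each strand;
* how far is a tag start from a gene's 3' end (longest splice variant);
* does a position fall in the sense downstream window (default 500 bp past
  the 3' end) of some gene.

Coordinates are 0-based half-open internally; GFF/GTF input (1-based
inclusive) is converted on load.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from intervaltree import IntervalTree

__all__ = [
    "AnnotationError",
    "TranscriptModel",
    "GeneModel",
    "OverlapResult",
    "AnnotationIndex",
    "load_annotation",
    "build_index",
    "tag_distance_from_3prime",
]

DEFAULT_WINDOW_BP = 500

_TRANSCRIPT_TYPES = {
    "mRNA",
    "transcript",
    "rRNA",
    "tRNA",
    "ncRNA",
    "snRNA",
    "snoRNA",
    "lnc_RNA",
    "miRNA",
    "pseudogenic_transcript",
}


class AnnotationError(ValueError):
    """Raised for malformed or structurally inconsistent annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """One splice variant: ordered disjoint exons and a strand-aware 3' end."""

    transcript_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be + or -, got {self.strand!r}"
            )
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: empty exon [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the 3' end (span end on +, span start on -)."""
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        """Summed exon length (nt)."""
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene with its splice variants.

    ``start``/``end`` are the gene limits: the full annotated span including
    introns and UTRs.  Tag assignment treats any sense alignment overlapping
    these limits as belonging to the gene.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: tuple[TranscriptModel, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: empty span [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for tx in self.transcripts:
            if tx.start < self.start or tx.end > self.end:
                raise AnnotationError(
                    f"transcript {tx.transcript_id} extends outside gene {self.gene_id}"
                )

    @property
    def three_prime_end(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def longest_transcript(self) -> TranscriptModel:
        """Longest splice variant by summed exon length; ties break on id."""
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        return min(self.transcripts, key=lambda t: (-t.length, t.transcript_id))

    def downstream_window(self, window_bp: int) -> tuple[int, int]:
        """Interval extending ``window_bp`` past the gene 3' end, sense strand."""
        if self.strand == "+":
            return self.end, self.end + window_bp
        return max(0, self.start - window_bp), self.start


@dataclass
class OverlapResult:
    """Genes recovered by an interval query, split by relation to the query strand."""

    sense: list[GeneModel] = field(default_factory=list)
    antisense: list[GeneModel] = field(default_factory=list)
    downstream: list[GeneModel] = field(default_factory=list)


class AnnotationIndex:
    """Indexed annotation: interval trees per (chrom, strand) plus 3'-end windows.

    Parameters
    ----------
    genes
        Gene models to index.
    window_bp
        Width of the sense downstream window past each gene's 3' end used to
        rescue apparently antisense tags that in fact extend a neighbouring
        gene's 3' UTR.
    rrna_gene_ids
        Explicit rRNA locus ids; genes with ``biotype == "rRNA"`` are flagged
        regardless.
    """

    def __init__(
        self,
        genes: Iterable[GeneModel],
        window_bp: int = DEFAULT_WINDOW_BP,
        rrna_gene_ids: Iterable[str] = (),
    ) -> None:
        self.window_bp = int(window_bp)
        self.genes: dict[str, GeneModel] = {}
        self.transcript_to_gene: dict[str, str] = {}
        self._span_trees: dict[tuple[str, str], IntervalTree] = {}
        self._window_trees: dict[tuple[str, str], IntervalTree] = {}
        self._chrom_spans: dict[str, list[tuple[int, int, str]]] = {}
        self.rrna_genes: set[str] = set(rrna_gene_ids)

        for gene in genes:
            if gene.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene id {gene.gene_id}")
            self.genes[gene.gene_id] = gene
            key = (gene.chrom, gene.strand)
            self._span_trees.setdefault(key, IntervalTree()).addi(
                gene.start, gene.end, gene
            )
            ws, we = gene.downstream_window(self.window_bp)
            if ws < we:
                self._window_trees.setdefault(key, IntervalTree()).addi(ws, we, gene)
            self._chrom_spans.setdefault(gene.chrom, []).append(
                (gene.start, gene.end, gene.gene_id)
            )
            for tx in gene.transcripts:
                if tx.transcript_id in self.transcript_to_gene:
                    raise AnnotationError(
                        f"transcript {tx.transcript_id} assigned to two genes"
                    )
                self.transcript_to_gene[tx.transcript_id] = gene.gene_id
            if gene.biotype == "rRNA":
                self.rrna_genes.add(gene.gene_id)
        for spans in self._chrom_spans.values():
            spans.sort()
        self.chroms: set[str] = {c for c, _ in self._span_trees}

    def __len__(self) -> int:
        return len(self.genes)

    def query_overlaps(
        self, chrom: str, start: int, end: int, strand: str
    ) -> OverlapResult:
        """Genes overlapping ``[start, end)`` relative to a read on ``strand``.

        ``sense``: same-strand genes whose limits overlap the interval.
        ``antisense``: opposite-strand genes overlapping it.
        ``downstream``: genes whose sense downstream window overlaps it (these
        are genes on the *query* strand, since their window is in their own
        sense orientation).
        """
        result = OverlapResult()
        if chrom not in self.chroms:
            warnings.warn(f"query on unknown chromosome {chrom!r}", stacklevel=2)
            return result
        other = "-" if strand == "+" else "+"
        for tree, bucket in (
            (self._span_trees.get((chrom, strand)), result.sense),
            (self._span_trees.get((chrom, other)), result.antisense),
            (self._window_trees.get((chrom, strand)), result.downstream),
        ):
            if tree is not None:
                bucket.extend(iv.data for iv in tree.overlap(start, end))
        for bucket in (result.sense, result.antisense, result.downstream):
            bucket.sort(key=lambda g: g.gene_id)
        return result

    def downstream_window_genes(
        self, chrom: str, pos: int, strand: str
    ) -> list[GeneModel]:
        """Genes on ``strand`` whose downstream window contains position ``pos``."""
        tree = self._window_trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda g: g.gene_id)

    def nearest_gene(self, chrom: str, start: int, end: int) -> tuple[str | None, int]:
        """Nearest gene (any strand) to ``[start, end)`` and its gap (0 if touching)."""
        spans = self._chrom_spans.get(chrom)
        if not spans:
            return None, -1
        best: tuple[int, str] | None = None
        i = bisect_left(spans, (start, start, ""))
        for j in range(max(0, i - 2), min(len(spans), i + 2)):
            gs, ge, gid = spans[j]
            gap = max(gs - end, start - ge, 0)
            if best is None or (gap, gid) < best:
                best = (gap, gid)
        return best[1], best[0]


def build_index(
    genes: Iterable[GeneModel],
    window_bp: int = DEFAULT_WINDOW_BP,
    rrna_gene_ids: Iterable[str] = (),
) -> AnnotationIndex:
    """Construct an :class:`AnnotationIndex` directly from gene models."""
    return AnnotationIndex(genes, window_bp=window_bp, rrna_gene_ids=rrna_gene_ids)


def _validate_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise AnnotationError(
                    f"{path.name}:{lineno}: expected >=8 tab-separated columns"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise AnnotationError(
                    f"{path.name}:{lineno}: end {end} < start {start}"
                )


def _first_attr(feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def load_annotation(
    annotation_file: str | Path,
    window_bp: int = DEFAULT_WINDOW_BP,
    rrna_gene_ids: Iterable[str] = (),
) -> AnnotationIndex:
    """Load a GFF3 or GTF annotation into an :class:`AnnotationIndex`.

    GFF3 files are expected to link features via ``ID``/``Parent``; GTF via
    ``gene_id``/``transcript_id``.  A transcript without exon children gets a
    single exon spanning its record.  Genes whose biotype attribute (or
    feature source column) marks them as rRNA are flagged for separate
    reporting of ribosomal reads.
    """
    path = Path(annotation_file)
    _validate_lines(path)
    is_gtf = path.suffix.lower() in {".gtf", ".gff2"}
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise AnnotationError(f"failed to parse {path.name}: {exc}") from exc

    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        gene_id = _first_attr(gf, "ID", "gene_id") or gf.id
        transcripts: list[TranscriptModel] = []
        for tf in db.children(gf, level=1):
            if tf.featuretype == "exon":
                continue
            if tf.featuretype not in _TRANSCRIPT_TYPES and not is_gtf:
                continue
            tid = _first_attr(tf, "ID", "transcript_id") or tf.id
            exons = sorted(
                (ex.start - 1, ex.end)
                for ex in db.children(tf, featuretype="exon")
            )
            if not exons:
                exons = [(tf.start - 1, tf.end)]
            transcripts.append(
                TranscriptModel(transcript_id=tid, strand=gf.strand, exons=tuple(exons))
            )
        if not transcripts:
            raise AnnotationError(f"gene {gene_id} has no transcripts with exons")
        biotype = (
            _first_attr(gf, "biotype", "gene_biotype", "locus_type")
            or "protein_coding"
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gf.seqid,
                strand=gf.strand,
                start=gf.start - 1,
                end=gf.end,
                transcripts=tuple(transcripts),
                biotype=biotype,
            )
        )
    # orphan transcripts: any transcript-type feature whose parent is not a gene
    known_tx = {t.transcript_id for g in genes for t in g.transcripts}
    for tf in db.features_of_type(tuple(_TRANSCRIPT_TYPES)):
        tid = _first_attr(tf, "ID", "transcript_id") or tf.id
        if tid not in known_tx:
            raise AnnotationError(f"transcript {tid} has no parent gene")
    return build_index(genes, window_bp=window_bp, rrna_gene_ids=rrna_gene_ids)


def tag_distance_from_3prime(tag_start: int, gene: GeneModel) -> int:
    """Signed distance from a tag start to the gene's 3' end.

    Measured against the longest splice variant's 3' end, strand-aware:
    positive means the tag starts upstream of the poly(A)-proximal end (inside
    the transcript), negative means downstream of it.
    """
    end3 = gene.longest_transcript.three_prime_end
    if gene.strand == "+":
        return end3 - tag_start
    return tag_start - end3
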