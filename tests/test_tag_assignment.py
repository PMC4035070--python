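import numpy as np
import pytest

from exprss.gene_models import build_index
from exprss.simulate import write_sam
from exprss.tag_assignment import (
    AlignedTag,
    Alignment,
    assign_library,
    assign_read,
    build_count_matrix,
)

from conftest import make_gene


def tag(read_id, *alignments):
    return AlignedTag(read_id, list(alignments))


def genome_aln(start, end, strand="+", chrom="chr1"):
    return Alignment(chrom, start, end, strand, "genome")


class TestAssignRead:
    def test_unique_sense_alignment(self, toy_index):
        a = assign_read(tag("r", genome_aln(1500, 1536)), toy_index)
        assert a.outcome == "assigned"
        assert a.targets == [("geneA", "sense", 1.0)]

    def test_paralog_split_equally(self, toy_index):
        a = assign_read(
            tag("r", genome_aln(1500, 1536), genome_aln(3100, 3136)), toy_index
        )
        assert a.outcome == "assigned"
        assert sorted(a.targets) == [("geneA", "sense", 0.5), ("geneB", "sense", 0.5)]

    def test_overlapping_gene_limits_split(self, toy_index):
        a = assign_read(tag("r", genome_aln(6850, 6886)), toy_index)
        assert sorted(g for g, _, _ in a.targets) == ["geneD", "geneE"]
        assert all(w == 0.5 for _, _, w in a.targets)

    def test_window_rescue_beats_antisense(self, toy_index):
        # read on + strand, antisense to geneC, but 200 bp past geneB's 3' end
        a = assign_read(tag("r", genome_aln(4200, 4236, "+")), toy_index)
        assert a.targets == [("geneB", "sense", 1.0)]

    def test_antisense_without_rescue(self, toy_index):
        # + strand read inside minus-strand geneF, no window nearby
        a = assign_read(tag("r", genome_aln(9300, 9336, "+")), toy_index)
        assert a.targets == [("geneF", "antisense", 1.0)]

    def test_more_than_max_genes_discarded(self):
        genes = [
            make_gene(f"g{i}", "chr1", "+", 1000 * i, 1000 * i + 500)
            for i in range(11)
        ]
        index = build_index(genes)
        alns = [genome_aln(1000 * i + 100, 1000 * i + 136) for i in range(11)]
        a = assign_read(tag("r", *alns), index)
        assert a.outcome == "discarded_multigene"
        assert a.targets == []

    def test_splice_variants_collapse_to_one_candidate(self):
        # two variants of one gene via the transcript pass count once
        genes = [make_gene("gX", "chr1", "+", 0, 2000, tx_ends=[1500, 2000])]
        index = build_index(genes)
        a = assign_read(
            tag(
                "r",
                Alignment("gX.1", 10, 46, "+", "transcript"),
                Alignment("gX.2", 10, 46, "+", "transcript"),
            ),
            index,
        )
        assert a.targets == [("gX", "sense", 1.0)]

    def test_no_overlap_is_unassigned(self, toy_index):
        a = assign_read(tag("r", genome_aln(100, 136)), toy_index)
        assert a.outcome == "unassigned" and a.targets == []

    def test_unknown_chrom_warns(self, toy_index):
        with pytest.warns(UserWarning):
            a = assign_read(tag("r", genome_aln(0, 36, chrom="chrZ")), toy_index)
        assert a.outcome == "unassigned"

    def test_strand_flip_swaps_sense_and_antisense(self, rng):
        """On an annotation without convergent neighbours, flipping every
        read's strand turns sense candidates into antisense ones."""
        genes = [
            make_gene(f"g{i}", "chr1", "+" if i % 2 else "-", 5000 * i, 5000 * i + 2000)
            for i in range(8)
        ]
        index = build_index(genes, window_bp=0)  # no window: isolate rules 1 and 3
        for _ in range(100):
            i = int(rng.integers(0, 8))
            start = 5000 * i + int(rng.integers(0, 1964))
            strand = "+" if rng.random() < 0.5 else "-"
            flipped = "-" if strand == "+" else "+"
            a = assign_read(tag("r", genome_aln(start, start + 36, strand)), index)
            b = assign_read(tag("r", genome_aln(start, start + 36, flipped)), index)
            swap = {"sense": "antisense", "antisense": "sense"}
            assert sorted((g, swap[o], w) for g, o, w in a.targets) == sorted(b.targets)


def brute_force_assign(tag, genes, tx2gene, window_bp=500, max_genes=10):
    """Independent straightforward re-implementation of the rule list."""
    candidates = []

    def add(gene_id, orientation):
        if (gene_id, orientation) not in candidates:
            candidates.append((gene_id, orientation))

    for aln in tag.alignments:
        if aln.source == "transcript":
            add(tx2gene[aln.ref], "sense" if aln.strand == "+" else "antisense")
            continue
        overlapping = [
            g for g in genes
            if g.chrom == aln.ref and g.start < aln.end and aln.start < g.end
        ]
        sense = [g for g in overlapping if g.strand == aln.strand]
        anti = [g for g in overlapping if g.strand != aln.strand]
        if sense:
            for g in sense:
                add(g.gene_id, "sense")
        elif anti:
            five = aln.start if aln.strand == "+" else aln.end - 1
            rescued = []
            for g in genes:
                if g.chrom != aln.ref or g.strand != aln.strand:
                    continue
                if g.strand == "+":
                    lo, hi = g.end, g.end + window_bp
                else:
                    lo, hi = max(0, g.start - window_bp), g.start
                if lo <= five < hi:
                    rescued.append(g.gene_id)
            if rescued:
                for gid in rescued:
                    add(gid, "sense")
            else:
                for g in anti:
                    add(g.gene_id, "antisense")
    if not candidates:
        return "unassigned", []
    if len({g for g, _ in candidates}) > max_genes:
        return "discarded_multigene", []
    w = 1.0 / len(candidates)
    return "assigned", sorted((g, o, w) for g, o in candidates)


def random_annotation(rng, n_genes=50):
    genes = []
    for i in range(n_genes):
        chrom = "chr1" if rng.random() < 0.7 else "chr2"
        start = int(rng.integers(0, 40_000))
        end = start + int(rng.integers(100, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"g{i}", chrom, strand, start, end))
    return genes


class TestOracleEquivalence:
    def test_cascade_matches_brute_force(self, rng):
        """The indexed rule cascade agrees with a linear-scan oracle on
        randomized annotations and reads."""
        genes = random_annotation(rng)
        index = build_index(genes, window_bp=500)
        tx2gene = {t.transcript_id: g.gene_id for g in genes for t in g.transcripts}
        for k in range(1000):
            n_aln = int(rng.integers(1, 5))
            alns = []
            for _ in range(n_aln):
                if rng.random() < 0.15:
                    g = genes[int(rng.integers(0, len(genes)))]
                    alns.append(
                        Alignment(g.transcripts[0].transcript_id, 0, 36,
                                  "+" if rng.random() < 0.8 else "-", "transcript")
                    )
                else:
                    chrom = "chr1" if rng.random() < 0.7 else "chr2"
                    start = int(rng.integers(0, 44_000))
                    strand = "+" if rng.random() < 0.5 else "-"
                    alns.append(Alignment(chrom, start, start + 36, strand, "genome"))
            t = tag(f"r{k}", *alns)
            a = assign_read(t, index)
            outcome, targets = brute_force_assign(t, genes, tx2gene)
            assert a.outcome == outcome
            # both sides compute the equal split as 1/len(candidates)
            assert sorted(a.targets) == targets


class TestWeightConservation:
    def test_assigned_weights_sum_to_one(self, rng):
        genes = random_annotation(rng)
        index = build_index(genes)
        for k in range(300):
            start = int(rng.integers(0, 44_000))
            strand = "+" if rng.random() < 0.5 else "-"
            a = assign_read(tag(f"r{k}", genome_aln(start, start + 36, strand)), index)
            if a.outcome == "assigned":
                assert sum(w for _, _, w in a.targets) == pytest.approx(1.0, abs=1e-9)
                weights = {w for _, _, w in a.targets}
                assert len(weights) == 1  # equal split


class TestCountMatrix:
    def test_unique_counts_accumulate(self, toy_index):
        asg = [
            assign_read(tag(f"r{i}", genome_aln(1500, 1536)), toy_index)
            for i in range(4)
        ]
        cm = build_count_matrix({"s1": asg})
        assert cm.layer("sense").loc["geneA", "s1"] == pytest.approx(4.0)
        assert cm.totals["s1"] == 4.0

    def test_split_read_conserves_mass(self, toy_index):
        a = assign_read(tag("r", genome_aln(6850, 6886)), toy_index)
        cm = build_count_matrix({"s1": [a]})
        sense = cm.layer("sense")["s1"]
        assert sense.loc["geneD"] == pytest.approx(0.5)
        assert sense.loc["geneE"] == pytest.approx(0.5)
        assert cm.df["s1"].to_numpy().sum() == pytest.approx(1.0)

    def test_tsv_round_trip_shape(self, toy_index, tmp_path):
        a = assign_read(tag("r", genome_aln(1500, 1536)), toy_index)
        cm = build_count_matrix({"s1": [a], "s2": []})
        path = tmp_path / "counts.tsv"
        cm.to_tsv(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["gene_id", "orientation", "s1", "s2"]


class TestAssignLibrary:
    def test_two_pass_and_summary(self, toy_index, tmp_path):
        genome_tags = [
            tag("r1", genome_aln(1500, 1536)),
            tag("r2", genome_aln(9300, 9336, "+")),
            tag("r3", genome_aln(100, 136)),
        ]
        tx_tags = [tag("r4", Alignment("geneA.1", 0, 36, "+", "transcript"))]
        gsam = tmp_path / "genome.sam"
        tsam = tmp_path / "tx.sam"
        write_sam(genome_tags, {"chr1": 50_000}, gsam)
        write_sam(tx_tags, {"geneA.1": 1000}, tsam)
        assignments, summary = assign_library(gsam, tsam, toy_index)
        assert summary["n_reads"] == 4
        assert summary["n_assigned"] == 3
        assert summary["n_unassigned"] == 1
        by_id = {a.read_id: a for a in assignments}
        assert by_id["r4"].targets == [("geneA", "sense", 1.0)]
        assert by_id["r2"].targets == [("geneF", "antisense", 1.0)]

    def test_read_in_both_passes_raises(self, toy_index, tmp_path):
        gsam = tmp_path / "genome.sam"
        tsam = tmp_path / "tx.sam"
        write_sam([tag("r1", genome_aln(1500, 1536))], {"chr1": 50_000}, gsam)
        write_sam(
            [tag("r1", Alignment("geneA.1", 0, 36, "+", "transcript"))],
            {"geneA.1": 1000},
            tsam,
        )
        with pytest.raises(ValueError, match="both passes"):
            assign_library(gsam, tsam, toy_index)

    def test_empty_transcript_pass_equals_genome_only(self, toy_index, tmp_path):
        gsam = tmp_path / "genome.sam"
        write_sam([tag("r1", genome_aln(1500, 1536))], {"chr1": 50_000}, gsam)
        assignments, _ = assign_library(gsam, None, toy_index)
        assert assignments[0].targets == [("geneA", "sense", 1.0)]
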