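import numpy as np
import pytest

from exprss.gene_models import build_index
from exprss.simulate import (
    align_reads_exact,
    make_transcriptome,
    simulate_library,
)
from exprss.tag_assignment import AlignedTag, Alignment, assign_read
from exprss.tag_profiles import (
    antisense_peak,
    call_apa_sites,
    detect_novel_regions,
    distance_profile,
    polya_sites_from_pairs,
)

from conftest import make_gene


class TestDistanceProfile:
    def test_tags_at_three_prime_end_fill_first_bin(self, toy_index):
        geneA = toy_index.genes["geneA"]  # + strand, 3' end 2000
        assignments = [
            assign_read(
                AlignedTag(f"r{i}", [Alignment("chr1", 1964, 2000, "+", "genome")]),
                toy_index,
            )
            for i in range(10)
        ]
        profile, summary = distance_profile(assignments, toy_index)
        assert profile.n_tags == 10
        # all tags start 36 bp upstream: single populated bin
        assert profile.counts.sum() == 10
        assert summary["modal_bin_left"] == 30

    def test_counts_sum_to_included_tags(self, toy_index, rng):
        assignments = []
        for i in range(50):
            start = 1000 + int(rng.integers(0, 964))
            assignments.append(
                assign_read(
                    AlignedTag(f"r{i}", [Alignment("chr1", start, start + 36, "+", "genome")]),
                    toy_index,
                )
            )
        profile, summary = distance_profile(assignments, toy_index)
        assert profile.counts.sum() == profile.n_tags == summary["n_tags"] == 50

    def test_multigene_and_antisense_tags_excluded(self, toy_index):
        multi = assign_read(
            AlignedTag("m", [Alignment("chr1", 6850, 6886, "+", "genome")]), toy_index
        )
        anti = assign_read(
            AlignedTag("a", [Alignment("chr1", 9300, 9336, "+", "genome")]), toy_index
        )
        profile, summary = distance_profile([multi, anti], toy_index)
        assert profile.n_tags == 0 and summary["defined"] is False

    def test_simulated_library_ninety_percent_within_300(self):
        """Random shearing places ~90% of unique sense tags within 300 bp."""
        tr = make_transcriptome(n_genes=40, paralog_fraction=0.0, apa_fraction=0.0,
                                antisense_fraction=0.0, seed=11)
        lib = simulate_library(tr, n_reads=8000, seed=12)
        tags, _ = align_reads_exact(lib.reads1, tr.chrom_sequences)
        assignments = [assign_read(t, tr.index) for t in tags]
        _, summary = distance_profile(assignments, tr.index)
        assert summary["fraction_within_300"] >= 0.90


class TestCallApaSites:
    def cluster(self, rng, center, n, sd=30):
        return np.round(rng.normal(center, sd, n)).astype(int)

    def test_two_well_separated_sites_both_called(self, rng):
        positions = np.concatenate(
            [self.cluster(rng, 2000, 50), self.cluster(rng, 2400, 50)]
        )
        calls = call_apa_sites(positions, strand="+")
        assert len(calls) == 2
        assert calls[0].kind == "primary" and calls[1].kind == "alternative"
        # 3'-most first on + strand
        assert calls[0].position > calls[1].position
        assert abs(calls[0].position - 2400) <= 25
        assert abs(calls[1].position - 2000) <= 25

    def test_sites_100bp_apart_collapse(self, rng):
        positions = np.concatenate(
            [self.cluster(rng, 2000, 50), self.cluster(rng, 2100, 50)]
        )
        calls = call_apa_sites(positions, strand="+")
        assert len(calls) == 1

    def test_single_cluster_primary_at_mode(self, rng):
        positions = self.cluster(rng, 1500, 50)
        calls = call_apa_sites(positions, strand="+")
        assert len(calls) == 1
        assert calls[0].kind == "primary"
        assert abs(calls[0].position - 1500) <= 25
        assert calls[0].support == 50 and calls[0].fraction == 1.0

    def test_pairwise_separation_invariant(self, rng):
        for trial in range(10):
            positions = rng.integers(0, 3000, 300)
            calls = call_apa_sites(positions, min_support=3, min_fraction=0.0)
            for a in calls:
                for b in calls:
                    if a is not b:
                        assert abs(a.position - b.position) > 200

    def test_agrees_with_exhaustive_oracle(self, rng):
        """Greedy-by-height selection matches brute-force enumeration of all
        smoothed local maxima plus optimal greedy on small histograms."""
        for trial in range(20):
            n = int(rng.integers(20, 200))
            positions = rng.integers(0, 2000, n)
            calls = call_apa_sites(positions, min_support=2, min_fraction=0.0)
            # oracle: full smoothed histogram, enumerate maxima, greedy
            bw = 25
            lo = (positions.min() // bw) * bw
            hi = (positions.max() // bw) * bw + bw
            edges = np.arange(lo, hi + bw, bw)
            counts, _ = np.histogram(positions, bins=edges)
            smoothed = np.convolve(counts, np.ones(3) / 3, mode="same")
            padded = np.concatenate([[-1.0], smoothed, [-1.0]])
            cands = []
            for i in range(len(smoothed)):
                if counts[i] == 0:
                    continue
                if padded[i + 1] >= padded[i] and padded[i + 1] >= padded[i + 2]:
                    support = counts[max(0, i - 1): i + 2].sum()
                    if support >= 2:
                        cands.append((-smoothed[i], -support, -(edges[i]), i))
            cands.sort()
            accepted = []
            for *_, i in cands:
                c = edges[i] + bw // 2
                if all(abs(c - a) > 200 for a in accepted):
                    accepted.append(c)
            assert sorted(c.position for c in calls) == sorted(int(a) for a in accepted)

    def test_empty_input(self):
        assert call_apa_sites([]) == []


class TestAntisensePeak:
    def test_clustered_antisense_tags_called(self, rng):
        positions = np.round(rng.normal(5000, 30, 100)).astype(int)
        call = antisense_peak(positions, strand="-", gene_id="g1")
        assert call is not None
        assert call.kind == "antisense"
        assert abs(call.position - 5000) <= 25

    def test_diffuse_tags_yield_no_call(self, rng):
        # 20 tags uniform over 5 kb: expected window mass ~0.3 tags < min_support
        positions = rng.integers(0, 5000, 20)
        assert antisense_peak(positions) is None

    def test_empty_input(self):
        assert antisense_peak([]) is None


class TestNovelRegions:
    def alns(self, starts, strand="+", chrom="chr1"):
        return [Alignment(chrom, s, s + 36, strand, "genome") for s in starts]

    def test_cluster_merged_and_supported(self):
        regions = detect_novel_regions(self.alns(range(10_000, 10_200, 10)))
        assert len(regions) == 1
        assert regions[0].support == 20

    def test_below_min_support_dropped(self):
        assert detect_novel_regions(self.alns([100, 110, 120, 130, 140])) == []

    def test_gap_above_merge_gap_splits(self):
        starts = list(range(1000, 1100, 10)) + list(range(1286, 1386, 10))
        regions = detect_novel_regions(self.alns(starts))
        assert len(regions) == 2

    def test_strands_kept_separate(self):
        mixed = self.alns(range(1000, 1100, 10)) + self.alns(
            range(1000, 1100, 10), strand="-"
        )
        regions = detect_novel_regions(mixed, min_support=10)
        assert {r.strand for r in regions} == {"+", "-"}

    def test_nearest_gene_annotated(self, toy_index):
        regions = detect_novel_regions(
            self.alns(range(2300, 2400, 10)), toy_index, min_support=5
        )
        assert regions[0].nearest_gene == "geneA"
        assert regions[0].distance_to_gene == 300


class TestPolyAFromPairs:
    def setup_index(self):
        # + strand gene, annotated 3' end at 5000
        return build_index([make_gene("gP", "chr1", "+", 3000, 5000)])

    def read2(self, site, n, rng):
        """Read-2 alignments whose 5'-most base (minus strand end) is at site."""
        out = []
        for i in range(n):
            jitter = int(rng.integers(-5, 6))
            end = site + jitter
            out.append(Alignment("chr1", end - 36, end + 1, "-", "genome"))
        return out

    def test_cluster_at_annotated_end_flagged(self, rng):
        index = self.setup_index()
        calls = polya_sites_from_pairs(self.read2(4999, 50, rng), index)
        assert len(calls) == 1
        assert calls[0].kind == "read2-derived"
        assert calls[0].annotated is True
        assert abs(calls[0].position - 5000) <= 25

    def test_upstream_cluster_flagged_novel(self, rng):
        index = self.setup_index()
        calls = polya_sites_from_pairs(self.read2(4700, 50, rng), index)
        assert len(calls) == 1
        assert calls[0].annotated is False
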