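"""Long RNAs spanning pre-miRNA hairpins: pairing, span patterns, calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rbctx.genome_model import GenomicInterval, PreMiRNALocus, overlap_length
from rbctx.joint_locus import (
    CoExpressionLocus,
    LongTranscriptCall,
    call_coexpression_loci,
    classify_span_pattern,
    find_spanning_transcripts,
    read_locus_report,
    render_locus_report,
    transcript_support,
)
from rbctx.mirna_catalog import MiRNACandidate, filter_candidates
from rbctx.synthetic_data import simulate_coexpression


def make_locus(start=10_000, strand="+", chrom="chr1", locus_id="m1"):
    arm, loop = 22, 20
    a = GenomicInterval(chrom, start, start + arm, strand)
    b = GenomicInterval(chrom, start + arm, start + arm + loop, strand)
    c = GenomicInterval(chrom, start + arm + loop, start + 2 * arm + loop, strand)
    hp = GenomicInterval(chrom, start, start + 2 * arm + loop, strand)
    if strand == "+":
        return PreMiRNALocus(locus_id, hp, a, b, c)
    return PreMiRNALocus(locus_id, hp, c, b, a)


def tx(start, end, strand="+", support=(100, 100, 100), tid="t1", chrom="chr1"):
    return LongTranscriptCall(tid, GenomicInterval(chrom, start, end, strand), tuple(support))


def mature_candidate(locus, score=2.0, counts=(100, 100, 100, 100, 100)):
    arm = locus.arm5p
    return MiRNACandidate(
        candidate_id=f"cand-{locus.locus_id}",
        score=score,
        hairpin_interval=locus.hairpin,
        mature_interval=GenomicInterval(arm.chrom, arm.start, arm.start + 22, locus.strand),
        arm="5p",
        mature_sequence="ACGUACGUACGUACGUACGUAC",
        read_counts=tuple(counts),
    )


class TestFindSpanning:
    def test_containing_transcript_paired(self):
        locus = make_locus()
        pairs = find_spanning_transcripts([tx(9_000, 11_000)], [locus])
        assert len(pairs) == 1

    def test_opposite_strand_excluded_by_default(self):
        locus = make_locus(strand="-")
        assert find_spanning_transcripts([tx(9_000, 11_000, "+")], [locus]) == []
        assert len(find_spanning_transcripts([tx(9_000, 11_000, "+")], [locus],
                                             same_strand=False)) == 1

    def test_matches_quadratic_oracle_on_random_features(self):
        rng = np.random.default_rng(31)
        loci = [make_locus(start=int(s), strand="+-"[rng.integers(2)], locus_id=f"m{i}")
                for i, s in enumerate(rng.integers(0, 50_000, 100))]
        txs = [tx(int(s), int(s) + int(l), "+-"[rng.integers(2)], tid=f"t{i}")
               for i, (s, l) in enumerate(zip(rng.integers(0, 50_000, 100),
                                              rng.integers(50, 2_000, 100)))]
        got = {(t.transcript_id, l.locus_id)
               for t, l in find_spanning_transcripts(txs, loci)}
        brute = {
            (t.transcript_id, l.locus_id)
            for t in txs for l in loci
            if t.strand == l.strand and overlap_length(t.interval, l.hairpin) > 0
        }
        assert got == brute


class TestSpanPattern:
    def test_full_span_with_wide_flanks(self):
        locus = make_locus()
        assert classify_span_pattern(tx(9_950, 10_114).interval, locus) == "FULL_SPAN"

    def test_transcript_inside_flank_margin_is_not_full_span(self):
        locus = make_locus()  # hairpin [10000, 10064)
        pattern = classify_span_pattern(tx(9_995, 10_069).interval, locus, flank=10)
        assert pattern == "PARTIAL_OTHER"

    def test_five_prime_only_plus_strand(self):
        locus = make_locus()
        # covers 5p arm and loop, stops before the 3p arm
        assert classify_span_pattern(tx(9_800, 10_042).interval, locus) == "FIVE_PRIME_ONLY"

    def test_five_prime_only_minus_strand(self):
        locus = make_locus(strand="-")  # 5p arm at larger coordinates
        iv = GenomicInterval("chr1", 10_042, 10_250, "-")
        assert classify_span_pattern(iv, locus) == "FIVE_PRIME_ONLY"

    def test_three_prime_arm_only_is_partial_other(self):
        locus = make_locus()
        iv = GenomicInterval("chr1", 10_050, 10_200)
        assert classify_span_pattern(iv, locus) == "PARTIAL_OTHER"

    def test_disjoint_transcript_rejected(self):
        with pytest.raises(ValueError):
            classify_span_pattern(GenomicInterval("chr1", 50_000, 50_100), make_locus())

    def test_full_span_implies_minimum_length(self):
        rng = np.random.default_rng(32)
        for _ in range(200):
            locus = make_locus(start=int(rng.integers(1_000, 40_000)),
                               strand="+-"[rng.integers(2)])
            s = int(rng.integers(locus.hairpin.start - 200, locus.hairpin.end))
            e = int(rng.integers(s + 10, locus.hairpin.end + 200))
            if overlap_length(GenomicInterval("chr1", s, e), locus.hairpin) == 0:
                continue
            pattern = classify_span_pattern(GenomicInterval("chr1", s, e), locus, flank=10)
            if pattern == "FULL_SPAN":
                assert e - s >= locus.hairpin.length + 20


class TestCalls:
    def test_strict_coverage_boundary(self):
        locus = make_locus()
        cand = mature_candidate(locus)
        above = [(tx(9_900, 10_200, support=(51, 51, 51)), locus)]
        at = [(tx(9_900, 10_200, support=(50, 50, 50)), locus)]
        assert len(call_coexpression_loci(above, [cand])) == 1
        assert call_coexpression_loci(at, [cand]) == []

    def test_unretained_mirna_blocks_call(self):
        locus = make_locus()
        weak = mature_candidate(locus, score=0.5, counts=(5, 5, 5, 5, 5))
        pairs = [(tx(9_900, 10_200, support=(200, 200, 200)), locus)]
        assert call_coexpression_loci(pairs, filter_candidates([weak])) == []

    def test_partial_other_excluded_unless_requested(self):
        locus = make_locus()
        cand = mature_candidate(locus)
        pairs = [(tx(10_050, 10_200, support=(90, 90, 90)), locus)]
        assert call_coexpression_loci(pairs, [cand]) == []
        included = call_coexpression_loci(pairs, [cand], include_partial=True)
        assert [c.pattern for c in included] == ["PARTIAL_OTHER"]

    def test_raising_coverage_min_never_adds(self):
        locus = make_locus()
        cand = mature_candidate(locus)
        pairs = [(tx(9_900, 10_200, support=(s, s, s), tid=f"t{s}"), locus)
                 for s in (30, 60, 90, 120)]
        sizes = [len(call_coexpression_loci(pairs, [cand], coverage_min=cm))
                 for cm in (0, 50, 80, 110, 200)]
        assert sizes == sorted(sizes, reverse=True)

    def test_aggregation_modes(self):
        locus = make_locus()
        cand = mature_candidate(locus)
        pairs = [(tx(9_900, 10_200, support=(10, 200, 30)), locus)]
        assert len(call_coexpression_loci(pairs, [cand], aggregation="mean")) == 1  # 80
        assert call_coexpression_loci(pairs, [cand], aggregation="min") == []
        assert len(call_coexpression_loci(pairs, [cand], aggregation="sum")) == 1

    def test_transcript_support_counts_overlapping_reads(self):
        iv = GenomicInterval("chr1", 1_000, 1_500)
        reads = {
            "s1": [GenomicInterval("chr1", 990, 1_040), GenomicInterval("chr1", 2_000, 2_050)],
            "s2": [GenomicInterval("chr1", 1_499, 1_549)],
        }
        assert transcript_support(iv, reads) == (1, 1)


class TestReport:
    def test_cluster_scenario_lists_four_elements(self, small_genome):
        transcripts, mirnas, truth = simulate_coexpression(small_genome)
        retained = filter_candidates(mirnas)
        pairs = find_spanning_transcripts(transcripts, small_genome.pre_mirna_loci)
        calls = call_coexpression_loci(pairs, retained)
        five = [c for c in calls if c.pattern == "FIVE_PRIME_ONLY"]
        assert len(five) == 1
        report = render_locus_report(five, transcripts, small_genome.pre_mirna_loci)
        assert len(report) == 4  # 3 clustered hairpins + 1 transcript
        assert (report["element_type"] == "pre_mirna").sum() == 3

    def test_empty_call_set_gives_empty_report(self):
        report = render_locus_report([], [], [])
        assert report.empty

    def test_report_round_trips_through_tsv(self, small_genome, tmp_path):
        transcripts, mirnas, _ = simulate_coexpression(small_genome)
        retained = filter_candidates(mirnas)
        pairs = find_spanning_transcripts(transcripts, small_genome.pre_mirna_loci)
        calls = call_coexpression_loci(pairs, retained)
        report = render_locus_report(calls, transcripts, small_genome.pre_mirna_loci)
        path = tmp_path / "report.tsv"
        report.to_csv(path, sep="\t", index=False)
        pd.testing.assert_frame_equal(read_locus_report(path), report)
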