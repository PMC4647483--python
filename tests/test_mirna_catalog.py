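"""Candidate filtering, known/putative partition, location, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rbctx.genome_model import GenomicInterval, GeneModel, ReferenceMiRNA, Transcript
from rbctx.mirna_catalog import (
    CatalogEntry,
    GenomicLocationClassifier,
    LOCATION_LABELS,
    MiRNACandidate,
    classify_genomic_location,
    classify_known_putative,
    filter_candidates,
    read_candidates,
    summarize_catalog,
    write_candidates,
)
from rbctx.synthetic_data import simulate_mirna_candidates


def candidate(score=2.0, counts=(100, 0, 0, 0, 0), chrom="chr1", start=1000,
              strand="+", sequence="ACGUACGUACGUACGUACGUAC", cid="c1"):
    return MiRNACandidate(
        candidate_id=cid,
        score=score,
        hairpin_interval=GenomicInterval(chrom, start, start + 66, strand),
        mature_interval=GenomicInterval(chrom, start, start + 22, strand),
        arm="5p",
        mature_sequence=sequence,
        read_counts=tuple(counts),
    )


class TestFilter:
    def test_both_boundaries_inclusive(self):
        keep = candidate(score=1.0, counts=(20, 0, 0, 0, 0))
        assert filter_candidates([keep]) == [keep]

    def test_score_below_cutoff_removed_despite_reads(self):
        assert filter_candidates([candidate(score=0.99, counts=(1000, 0, 0, 0, 0))]) == []

    def test_read_rule_is_per_sample_max_not_sum(self):
        spread = candidate(score=5.0, counts=(19, 19, 19, 19, 19))
        assert filter_candidates([spread]) == []
        assert filter_candidates([spread], pooled=True) == [spread]

    def test_idempotent_and_subset(self):
        cands = [candidate(score=s, counts=(c, 0, 0, 0, 0), cid=f"c{i}")
                 for i, (s, c) in enumerate([(0.5, 30), (1.5, 10), (2.0, 50), (1.0, 20)])]
        once = filter_candidates(cands)
        assert set(once) <= set(cands)
        assert filter_candidates(once) == once

    def test_raising_thresholds_never_adds(self):
        rng = np.random.default_rng(3)
        cands = [
            candidate(score=float(rng.uniform(0, 3)),
                      counts=tuple(int(x) for x in rng.integers(0, 60, 5)),
                      cid=f"c{i}")
            for i in range(40)
        ]
        base = set(c.candidate_id for c in filter_candidates(cands))
        for ms, mr in [(1.5, 20), (1.0, 40), (2.0, 50)]:
            tighter = set(c.candidate_id for c in filter_candidates(cands, ms, mr))
            assert tighter <= base


class TestKnownPutative:
    reference = [
        ReferenceMiRNA(
            mir_id="ref1",
            mature_sequence="ACGUACGUACGUACGUACGUAC",
            mature_interval=GenomicInterval("chr9", 500, 522),
            hairpin_interval=GenomicInterval("chr9", 500, 566),
        )
    ]

    def test_sequence_match_at_different_locus_is_known(self):
        c = candidate(chrom="chr2", sequence="ACGUACGUACGUACGUACGUAC")
        assert classify_known_putative(c, self.reference) == "known"

    def test_same_strand_hairpin_overlap_is_known_despite_sequence(self):
        c = candidate(chrom="chr9", start=540, sequence="UUUUACGUACGUACGUACGUAC")
        assert classify_known_putative(c, self.reference) == "known"

    def test_opposite_strand_overlap_is_putative(self):
        c = candidate(chrom="chr9", start=540, strand="-",
                      sequence="UUUUACGUACGUACGUACGUAC")
        assert classify_known_putative(c, self.reference) == "putative"

    def test_no_match_no_overlap_is_putative(self):
        c = candidate(chrom="chr3", sequence="UUUUACGUACGUACGUACGUAC")
        assert classify_known_putative(c, self.reference) == "putative"


def make_annotation():
    """chr1: coding gene with UTR/CDS/intron; lncRNA; both on '+'."""
    coding = GeneModel(
        "pc", "protein_coding",
        (Transcript(
            "pc.t1",
            exons=(GenomicInterval("chr1", 1000, 1400), GenomicInterval("chr1", 2000, 2400)),
            cds=(GenomicInterval("chr1", 1200, 1400), GenomicInterval("chr1", 2000, 2200)),
        ),),
    )
    lnc = GeneModel(
        "lnc", "lncRNA",
        (Transcript("lnc.t1", exons=(GenomicInterval("chr1", 5000, 5600),)),),
    )
    return [coding, lnc]


class TestGenomicLocation:
    genes = make_annotation()

    @pytest.mark.parametrize(
        "start, end, expected",
        [
            (1150, 1250, "coding"),     # spans UTR and CDS: coding wins
            (1390, 1450, "coding"),     # spans CDS and intron: coding wins
            (1050, 1100, "utr"),
            (1500, 1550, "intronic"),
            (5100, 5150, "lncRNA"),
            (9000, 9050, "intergenic"),
        ],
    )
    def test_precedence(self, start, end, expected):
        iv = GenomicInterval("chr1", start, end)
        assert classify_genomic_location(iv, self.genes) == expected

    def test_matches_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(12)
        clf = GenomicLocationClassifier(self.genes)
        for _ in range(500):
            start = int(rng.integers(0, 10_000))
            iv = GenomicInterval("chr1", start, start + 22)
            assert clf.classify(iv) == brute_force_location_label(iv, self.genes)


def brute_force_location_label(iv, genes):
    """Independent per-base feature enumeration with the stated precedence."""
    bases = set(range(iv.start, iv.end))
    present = set()
    for g in genes:
        if g.chrom != iv.chrom:
            continue
        exon = set()
        cds = set()
        for t in g.transcripts:
            for e in t.exons:
                exon |= set(range(e.start, e.end))
            for c in t.cds:
                cds |= set(range(c.start, c.end))
        body = set(range(g.span.start, g.span.end))
        if g.biotype == "protein_coding":
            if bases & cds:
                present.add("coding")
            if bases & (exon - cds):
                present.add("utr")
        elif g.biotype == "lncRNA":
            if bases & exon:
                present.add("lncRNA")
        if bases & body:
            present.add("intronic")
    for label in LOCATION_LABELS[:-1]:
        if label in present:
            return label
    return "intergenic"


class TestSummaries:
    def build_entries(self):
        cands = [
            candidate(cid="m1", counts=(80, 90, 70, 60, 100)),
            candidate(cid="m2", counts=(20, 10, 30, 40, 0), start=2000),
            candidate(cid="m3", counts=(5, 5, 5, 5, 5), start=3000),
        ]
        return [
            CatalogEntry(cands[0], "known", "intergenic"),
            CatalogEntry(cands[1], "known", "intronic"),
            CatalogEntry(cands[2], "putative", "intergenic"),
        ]

    def test_single_mirna_holds_all_reads(self):
        entry = CatalogEntry(candidate(cid="only", counts=(50, 60, 70, 80, 90)),
                             "known", "intergenic")
        tables = summarize_catalog([entry])
        assert np.allclose(tables["top10_read_pct"].loc["only"], 100.0)

    def test_location_percentages_sum_to_100_per_status(self):
        tables = summarize_catalog(self.build_entries())
        assert np.allclose(tables["location_pct"].sum(axis=1), 100.0)

    def test_percentages_match_hand_tally(self):
        tables = summarize_catalog(self.build_entries())
        # sample 1: known mature reads = 80 + 20 = 100
        assert tables["top10_read_pct"].loc["m1"].iloc[0] == pytest.approx(80.0)
        assert tables["top10_read_pct"].loc["m3"].iloc[0] == pytest.approx(5.0)
        assert tables["location_pct"].loc["known", "intronic"] == pytest.approx(50.0)

    def test_empty_catalog(self):
        tables = summarize_catalog([])
        assert tables["location_pct"].empty

    def test_synthetic_catalog_matches_planted_truth(self, small_genome):
        candidates, truth = simulate_mirna_candidates(small_genome)
        entries = [
            CatalogEntry(c, truth.loc[c.candidate_id, "status"],
                         truth.loc[c.candidate_id, "location"])
            for c in candidates
        ]
        tables = summarize_catalog(entries)
        for status in ("known", "putative"):
            sub = truth[truth["status"] == status]
            for label in LOCATION_LABELS:
                expected = 100 * (sub["location"] == label).mean()
                assert tables["location_pct"].loc[status, label] == pytest.approx(expected)


class TestRoundTrip:
    def test_candidates_tsv_round_trip(self, small_genome, tmp_path):
        candidates, _ = simulate_mirna_candidates(small_genome)
        path = tmp_path / "cands.tsv"
        samples = [f"S{i}" for i in range(5)]
        write_candidates(candidates, path, samples)
        again, sample_ids = read_candidates(path)
        assert again == candidates
        assert sample_ids == samples
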