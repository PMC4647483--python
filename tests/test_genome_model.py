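"""Coordinate model, interval arithmetic, and file round trips."""

from __future__ import annotations

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbctx.genome_model import (
    GenomeIndex,
    GenomicInterval,
    GeneModel,
    GTFParseError,
    PreMiRNALocus,
    Transcript,
    ValidationError,
    merge_intervals,
    overlap_length,
    read_annotation,
    read_bed,
    subtract_intervals,
    write_annotation,
    write_bed,
)


def interval(chrom="chr1", start=0, end=10, strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestGenomicInterval:
    def test_length_and_validation(self):
        assert interval(start=100, end=200).length == 100
        with pytest.raises(ValidationError):
            interval(start=5, end=5)
        with pytest.raises(ValidationError):
            interval(start=7, end=3)
        with pytest.raises(ValidationError):
            interval(strand="*")

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 10), (10, 20), 0),  # half-open abutment
            ((0, 10), (5, 8), 3),
            ((5, 8), (0, 10), 3),
            ((0, 10), (0, 10), 10),
        ],
    )
    def test_overlap_examples(self, a, b, expected):
        assert overlap_length(interval(start=a[0], end=a[1]), interval(start=b[0], end=b[1])) == expected

    def test_overlap_cross_chromosome_is_zero(self):
        assert overlap_length(interval("chr1"), interval("chr2")) == 0

    @given(
        s1=st.integers(0, 300), l1=st.integers(1, 100),
        s2=st.integers(0, 300), l2=st.integers(1, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_overlap_matches_per_base_count(self, s1, l1, s2, l2):
        a, b = interval(start=s1, end=s1 + l1), interval(start=s2, end=s2 + l2)
        brute = len(set(range(a.start, a.end)) & set(range(b.start, b.end)))
        assert overlap_length(a, b) == brute
        assert overlap_length(a, b) == overlap_length(b, a)
        assert overlap_length(a, b) <= min(a.length, b.length)


class TestIntervalSetOps:
    @given(st.lists(st.tuples(st.integers(0, 200), st.integers(1, 40)), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_merge_equals_base_union(self, raw):
        ivs = [interval(start=s, end=s + l) for s, l in raw]
        merged = merge_intervals(ivs)
        base_truth = set().union(*(range(i.start, i.end) for i in ivs))
        base_merged = set().union(*(range(i.start, i.end) for i in merged))
        assert base_merged == base_truth
        assert all(a.end < b.start for a, b in zip(merged, merged[1:]))  # disjoint sorted

    @given(
        st.lists(st.tuples(st.integers(0, 200), st.integers(1, 40)), min_size=1, max_size=6),
        st.lists(st.tuples(st.integers(0, 200), st.integers(1, 40)), max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_subtract_equals_base_difference(self, raw_a, raw_b):
        a = [interval(start=s, end=s + l) for s, l in raw_a]
        b = [interval(start=s, end=s + l) for s, l in raw_b]
        out = subtract_intervals(a, b)
        base_a = set().union(*(range(i.start, i.end) for i in a))
        base_b = set().union(*(range(i.start, i.end) for i in b)) if b else set()
        base_out = set().union(*(range(i.start, i.end) for i in out)) if out else set()
        assert base_out == base_a - base_b


class TestGeneModel:
    def test_shared_exon_counted_once(self):
        exon = interval(start=100, end=300)
        t1 = Transcript("t1", (exon,))
        t2 = Transcript("t2", (exon, interval(start=400, end=500)))
        gene = GeneModel("g", "other_ncRNA", (t1, t2))
        assert gene.exonic_length == 300  # 200 shared once + 100

    def test_strand_aware_tss_tes(self):
        tx = Transcript("t", (interval(start=100, end=200, strand="-"),))
        gene = GeneModel("g", "other_ncRNA", (tx,))
        assert gene.tss == 200 and gene.tes == 100

    def test_utr_is_exonic_minus_cds(self):
        exons = (interval(start=0, end=100), interval(start=200, end=300))
        cds = (interval(start=50, end=100), interval(start=200, end=250))
        gene = GeneModel("g", "protein_coding", (Transcript("t", exons, cds),))
        utr_bases = set().union(*(range(i.start, i.end) for i in gene.utr_union))
        assert utr_bases == set(range(0, 50)) | set(range(250, 300))

    def test_cds_outside_exon_rejected(self):
        with pytest.raises(ValidationError):
            Transcript("t", (interval(start=0, end=100),), (interval(start=50, end=150),))


class TestPreMiRNALocus:
    def make(self, strand="+"):
        a = interval(start=0, end=22, strand=strand)
        b = interval(start=22, end=40, strand=strand)
        c = interval(start=40, end=62, strand=strand)
        hp = interval(start=0, end=62, strand=strand)
        if strand == "+":
            return PreMiRNALocus("m", hp, a, b, c)
        return PreMiRNALocus("m", hp, c, b, a)

    def test_parts_tile_hairpin_both_strands(self):
        for strand in "+-":
            locus = self.make(strand)
            parts = sorted([locus.arm5p, locus.loop, locus.arm3p], key=lambda i: i.start)
            assert parts[0].start == locus.hairpin.start
            assert parts[-1].end == locus.hairpin.end

    def test_minus_strand_5p_arm_has_larger_coordinates(self):
        locus = self.make("-")
        assert locus.arm5p.start > locus.arm3p.start

    def test_gap_between_parts_rejected(self):
        a = interval(start=0, end=22)
        b = interval(start=25, end=40)  # gap 22..25
        c = interval(start=40, end=62)
        with pytest.raises(ValidationError):
            PreMiRNALocus("m", interval(start=0, end=62), a, b, c)


class TestGTF:
    def test_coordinate_convention(self, tmp_path):
        gtf = tmp_path / "one.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t"; '
            'gene_biotype "protein_coding";\n'
        )
        genes = read_annotation(gtf)
        assert genes[0].transcripts[0].exons[0] == interval(start=100, end=200)

    def test_malformed_line_names_line_number(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text("chr1\tsrc\texon\t101\t200\n")
        with pytest.raises(GTFParseError, match="line 1"):
            read_annotation(gtf)

    def test_inverted_coordinates_rejected(self, tmp_path):
        gtf = tmp_path / "inv.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t200\t101\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValidationError, match="line 1"):
            read_annotation(gtf)

    def test_round_trip(self, small_genome, tmp_path):
        path = tmp_path / "genome.gtf"
        write_annotation(small_genome.genes, path)
        again = read_annotation(path)
        assert again == small_genome.genes

    def test_gzip_transparent(self, small_genome, tmp_path):
        path = tmp_path / "genome.gtf.gz"
        write_annotation(small_genome.genes, path)
        with gzip.open(path, "rt") as fh:
            assert fh.readline().startswith("chr")
        assert read_annotation(path) == small_genome.genes


class TestBED:
    def test_format_line(self, tmp_path):
        path = tmp_path / "x.bed"
        write_bed([(interval(start=100, end=200), "name")], path)
        assert path.read_text() == "chr1\t100\t200\tname\t0\t+\n"

    def test_empty(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_bed([], path)
        assert path.read_text() == ""
        assert read_bed(path) == []

    def test_round_trip_is_sorted_identity(self, tmp_path):
        rng = np.random.default_rng(5)
        records = [
            (interval(chrom=f"chr{rng.integers(1, 3)}", start=int(s), end=int(s) + 50,
                      strand="+-"[rng.integers(2)]), f"r{i}")
            for i, s in enumerate(rng.integers(0, 10_000, size=40))
        ]
        path = tmp_path / "r.bed"
        write_bed(records, path)
        expected = sorted(records, key=lambda r: (r[0].chrom, r[0].start, r[0].end, r[1]))
        assert read_bed(path) == expected


class TestGenomeIndex:
    def test_matches_linear_scan_on_random_queries(self):
        rng = np.random.default_rng(7)
        features = [
            interval(chrom=f"chr{rng.integers(1, 4)}", start=int(s), end=int(s + l))
            for s, l in zip(rng.integers(0, 50_000, 300), rng.integers(1, 500, 300))
        ]
        index = GenomeIndex()
        for i, iv in enumerate(features):
            index.add(iv, i)
        for _ in range(1000):
            start = int(rng.integers(0, 50_000))
            q = interval(
                chrom=f"chr{rng.integers(1, 4)}",
                start=start,
                end=start + int(rng.integers(1, 800)),
            )
            linear = {i for i, iv in enumerate(features) if overlap_length(q, iv) > 0}
            assert set(index.query(q)) == linear
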