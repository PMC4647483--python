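"""Genomic coordinate model and flat-file I/O.

Every analysis in this package works on a single internal coordinate
convention: 0-based, half-open ``[start, end)`` intervals, the BED
convention.  GTF input/output converts to and from the 1-based inclusive
convention at the file boundary and nowhere else.

The domain types are deliberately small: an interval, a gene model with
exon/CDS structure, a pre-miRNA hairpin with its 5p-arm/loop/3p-arm
partition, and a reference mature miRNA.  Strand is stored on every type
but overlap arithmetic is strand-blind; each downstream classifier states
its own strand policy.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "PreMiRNALocus",
    "ReferenceMiRNA",
    "GTFParseError",
    "ValidationError",
    "overlap_length",
    "merge_intervals",
    "subtract_intervals",
    "GenomeIndex",
    "read_annotation",
    "write_annotation",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
]

BIOTYPES = ("protein_coding", "lncRNA", "other_ncRNA")


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class GTFParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on one strand.

    ``start < end`` is enforced, so every interval has length >= 1.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals; 0 across chromosomes.

    Strand is ignored: callers that need strand-aware overlap filter on
    strand before calling.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint intervals.

    Strand of each merged run is taken from its first member; merging
    across strands is the caller's decision by construction of the input.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end, cur_strand = ivs[0].start, ivs[0].end, ivs[0].strand
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end, cur_strand))
                cur_start, cur_end, cur_strand = iv.start, iv.end, iv.strand
        out.append(GenomicInterval(chrom, cur_start, cur_end, cur_strand))
    return out


def subtract_intervals(
    minuend: Sequence[GenomicInterval], subtrahend: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference minuend \\ subtrahend, both treated as base sets."""
    sub_merged = merge_intervals(subtrahend) if subtrahend else []
    out: list[GenomicInterval] = []
    for iv in merge_intervals(minuend) if minuend else []:
        cursor = iv.start
        for s in sub_merged:
            if s.chrom != iv.chrom or s.end <= cursor or s.start >= iv.end:
                continue
            if s.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, s.start, iv.strand))
            cursor = max(cursor, s.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end, iv.strand))
    return out


@dataclass(frozen=True)
class Transcript:
    """One transcript: sorted non-overlapping exons, optional CDS."""

    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                raise ValidationError(
                    f"transcript {self.transcript_id}: CDS {c} not contained in any exon"
                )

    @property
    def span(self) -> GenomicInterval:
        e0, e1 = self.exons[0], self.exons[-1]
        return GenomicInterval(e0.chrom, e0.start, e1.end, e0.strand)


@dataclass(frozen=True)
class GeneModel:
    """A gene: biotype, strand, and one or more transcripts.

    UTR is always derived (exonic minus CDS), never parsed from the file.
    """

    gene_id: str
    biotype: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"gene {self.gene_id}: biotype {self.biotype!r} not in {BIOTYPES}"
            )
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id} has no transcripts")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].exons[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        """Gene body: leftmost exon start to rightmost exon end."""
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: 5' end of the gene body."""
        s = self.span
        return s.start if self.strand == "+" else s.end

    @property
    def tes(self) -> int:
        """Strand-aware transcription end: 3' end of the gene body."""
        s = self.span
        return s.end if self.strand == "+" else s.start

    @property
    def exon_union(self) -> list[GenomicInterval]:
        return merge_intervals(e for t in self.transcripts for e in t.exons)

    @property
    def exonic_length(self) -> int:
        return sum(iv.length for iv in self.exon_union)

    @property
    def cds_union(self) -> list[GenomicInterval]:
        cds = [c for t in self.transcripts for c in t.cds]
        return merge_intervals(cds) if cds else []

    @property
    def utr_union(self) -> list[GenomicInterval]:
        """Exonic bases of coding transcripts that are not CDS."""
        if self.biotype != "protein_coding":
            return []
        return subtract_intervals(self.exon_union, self.cds_union)

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gene-body bases not covered by any exon of any transcript."""
        return subtract_intervals([self.span], self.exon_union)


@dataclass(frozen=True)
class PreMiRNALocus:
    """A pre-miRNA hairpin partitioned into 5p arm, loop, and 3p arm.

    The three parts are disjoint, contiguous, and tile the hairpin.  Arm
    labels are strand-aware: on the minus strand the 5p arm occupies the
    larger genomic coordinates.
    """

    locus_id: str
    hairpin: GenomicInterval
    arm5p: GenomicInterval
    loop: GenomicInterval
    arm3p: GenomicInterval

    def __post_init__(self) -> None:
        strand = self.hairpin.strand
        if strand == "+":
            ordered = (self.arm5p, self.loop, self.arm3p)
        else:
            ordered = (self.arm3p, self.loop, self.arm5p)
        if ordered[0].start != self.hairpin.start or ordered[-1].end != self.hairpin.end:
            raise ValidationError(f"locus {self.locus_id}: parts do not tile the hairpin")
        for a, b in zip(ordered, ordered[1:]):
            if a.end != b.start:
                raise ValidationError(
                    f"locus {self.locus_id}: parts not contiguous ({a.end} != {b.start})"
                )
        for part in ordered:
            if part.chrom != self.hairpin.chrom:
                raise ValidationError(f"locus {self.locus_id}: part on wrong chromosome")

    @property
    def strand(self) -> str:
        return self.hairpin.strand


RNA_ALPHABET = set("ACGU")


@dataclass(frozen=True)
class ReferenceMiRNA:
    """A mature miRNA from the reference set (miRBase-like record)."""

    mir_id: str
    mature_sequence: str
    mature_interval: GenomicInterval
    hairpin_interval: GenomicInterval

    def __post_init__(self) -> None:
        n = len(self.mature_sequence)
        if not 18 <= n <= 24:
            raise ValidationError(
                f"{self.mir_id}: mature sequence length {n} outside 18-24 nt"
            )
        bad = set(self.mature_sequence) - RNA_ALPHABET
        if bad:
            raise ValidationError(f"{self.mir_id}: non-ACGU characters {sorted(bad)}")

    @property
    def strand(self) -> str:
        return self.mature_interval.strand


class GenomeIndex:
    """Interval-tree index over arbitrary payloads keyed by interval."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, interval: GenomicInterval, payload) -> None:
        self._trees.setdefault(interval.chrom, IntervalTree()).addi(
            interval.start, interval.end, payload
        )

    def query(self, interval: GenomicInterval) -> list:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(interval.start, interval.end)]


# ---------------------------------------------------------------------------
# File I/O: GTF, BED6, FASTA (all gzip-transparent)
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def _canonical_biotype(raw: str) -> str:
    if raw == "protein_coding":
        return "protein_coding"
    if raw in ("lncRNA", "lincRNA", "antisense"):
        return "lncRNA"
    return "other_ncRNA"


def read_annotation(gtf_path) -> list[GeneModel]:
    """Read gene models from an Ensembl-dialect GTF file.

    GTF coordinates (1-based, inclusive) are converted to the internal
    0-based half-open convention.  Only exon and CDS features build the
    models; gene/transcript container lines are tolerated but not
    required.  Genes without any exon are rejected.

    Raises
    ------
    GTFParseError
        On a malformed line; the message names the 1-based line number.
    ValidationError
        On inverted coordinates or invariant violations.
    """
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    cds: dict[tuple[str, str], list[GenomicInterval]] = {}
    biotype: dict[str, str] = {}
    gene_order: list[str] = []
    tx_order: dict[str, list[str]] = {}

    with _open_text(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GTFParseError(f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ValidationError(f"line {lineno}: end {end1} < start {start1}")
            attrs = _parse_attributes(attrs_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GTFParseError(f"line {lineno}: missing gene_id attribute")
            if gene_id not in biotype:
                biotype[gene_id] = _canonical_biotype(attrs.get("gene_biotype", "other"))
                gene_order.append(gene_id)
                tx_order[gene_id] = []
            elif "gene_biotype" in attrs:
                biotype[gene_id] = _canonical_biotype(attrs["gene_biotype"])
            if feature not in ("exon", "CDS"):
                continue
            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                raise GTFParseError(f"line {lineno}: {feature} without transcript_id")
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            key = (gene_id, tx_id)
            if tx_id not in tx_order[gene_id]:
                tx_order[gene_id].append(tx_id)
            (exons if feature == "exon" else cds).setdefault(key, []).append(iv)

    genes: list[GeneModel] = []
    for gene_id in gene_order:
        transcripts = []
        for tx_id in tx_order[gene_id]:
            key = (gene_id, tx_id)
            if key not in exons:
                continue
            transcripts.append(
                Transcript(
                    transcript_id=tx_id,
                    exons=tuple(sorted(exons[key], key=lambda i: i.start)),
                    cds=tuple(sorted(cds.get(key, []), key=lambda i: i.start)),
                )
            )
        if not transcripts:
            continue  # gene with zero exons: rejected
        genes.append(
            GeneModel(gene_id=gene_id, biotype=biotype[gene_id], transcripts=tuple(transcripts))
        )
    return genes


def write_annotation(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as Ensembl-dialect GTF (inverse of read_annotation)."""
    with _open_text(path, "wt") as fh:
        for gene in genes:
            span = gene.span
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            fh.write(
                f"{span.chrom}\trbctx\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            for tx in gene.transcripts:
                tattrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_biotype "{gene.biotype}";'
                )
                ts = tx.span
                fh.write(
                    f"{ts.chrom}\trbctx\ttranscript\t{ts.start + 1}\t{ts.end}\t.\t"
                    f"{gene.strand}\t.\t{tattrs}\n"
                )
                for feature, ivs in (("exon", tx.exons), ("CDS", tx.cds)):
                    for iv in ivs:
                        fh.write(
                            f"{iv.chrom}\trbctx\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
                            f"{gene.strand}\t.\t{tattrs}\n"
                        )


def write_bed(records: Iterable[tuple[GenomicInterval, str]], path) -> None:
    """Write (interval, name) records as BED6, score 0, deterministic order."""
    rows = sorted(
        ((iv.chrom, iv.start, iv.end, name, iv.strand) for iv, name in records),
        key=lambda r: (r[0], r[1], r[2], r[3]),
    )
    with _open_text(path, "wt") as fh:
        for chrom, start, end, name, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def read_bed(path) -> list[tuple[GenomicInterval, str]]:
    """Read BED6 (or BED4+) records as (interval, name) pairs."""
    out: list[tuple[GenomicInterval, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"BED line {lineno}: fewer than 4 fields")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "+"
            out.append((GenomicInterval(chrom, int(start), int(end), strand), name))
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences
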