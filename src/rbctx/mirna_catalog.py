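"""miRNA candidate cataloguing: score/read filtering, known-vs-putative
partition, genomic-location classification, and abundance summaries.

Candidates arrive as miRDeep-style records (a log-odds-like hairpin
score, the hairpin and mature intervals, the mature sequence, and mature
read counts per sample); this module does not re-derive them from raw
reads.  The retention rule is the discovery cutoff used for erythrocyte
short-RNA libraries: score >= 1 and >= 20 reads in at least one sample,
both boundaries inclusive.

A candidate is *known* when its mature sequence exactly matches a
reference mature sequence, or its hairpin overlaps a reference hairpin
on the same strand; otherwise it is *putative*.  Genomic location uses
the precedence coding > utr > lncRNA > intronic > intergenic, so a
mature sequence touching both an intron and a coding exon of alternative
transcripts is listed as coding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genome_model import (
    GeneModel,
    GenomeIndex,
    GenomicInterval,
    ReferenceMiRNA,
    ValidationError,
    overlap_length,
)

__all__ = [
    "MiRNACandidate",
    "CatalogEntry",
    "filter_candidates",
    "classify_known_putative",
    "GenomicLocationClassifier",
    "classify_genomic_location",
    "build_catalog",
    "summarize_catalog",
    "read_candidates",
    "write_candidates",
    "LOCATION_LABELS",
]

LOCATION_LABELS = ("coding", "utr", "lncRNA", "intronic", "intergenic")


@dataclass(frozen=True)
class MiRNACandidate:
    """One miRDeep-style candidate record."""

    candidate_id: str
    score: float
    hairpin_interval: GenomicInterval
    mature_interval: GenomicInterval
    arm: str  # "5p" | "3p"
    mature_sequence: str
    read_counts: tuple[int, ...]  # one entry per sample, fixed order

    def __post_init__(self) -> None:
        if not self.hairpin_interval.contains(self.mature_interval):
            raise ValidationError(
                f"{self.candidate_id}: mature interval not inside hairpin"
            )
        if not 18 <= len(self.mature_sequence) <= 24:
            raise ValidationError(
                f"{self.candidate_id}: mature length {len(self.mature_sequence)} "
                "outside 18-24 nt"
            )
        if self.arm not in ("5p", "3p"):
            raise ValidationError(f"{self.candidate_id}: arm must be 5p or 3p")
        if any(c < 0 for c in self.read_counts):
            raise ValidationError(f"{self.candidate_id}: negative read count")

    @property
    def strand(self) -> str:
        return self.hairpin_interval.strand

    @property
    def max_reads(self) -> int:
        return max(self.read_counts) if self.read_counts else 0

    @property
    def total_reads(self) -> int:
        return sum(self.read_counts)


@dataclass(frozen=True)
class CatalogEntry:
    candidate: MiRNACandidate
    status: str  # "known" | "putative"
    location: str  # one of LOCATION_LABELS


def filter_candidates(
    candidates: Sequence[MiRNACandidate],
    min_score: float = 1.0,
    min_reads: int = 20,
    pooled: bool = False,
) -> list[MiRNACandidate]:
    """Retain candidates with score >= min_score and enough mature reads.

    The read requirement is per-sample by default ("in at least one
    sample"): the maximum single-sample count must reach ``min_reads``.
    ``pooled=True`` instead tests the sum over samples, for sensitivity
    analysis only.
    """
    def enough_reads(c: MiRNACandidate) -> bool:
        return (c.total_reads if pooled else c.max_reads) >= min_reads

    return [c for c in candidates if c.score >= min_score and enough_reads(c)]


def classify_known_putative(
    candidate: MiRNACandidate, reference: Sequence[ReferenceMiRNA]
) -> str:
    """'known' on an exact mature-sequence match anywhere, or a same-strand
    hairpin overlap with a reference hairpin; otherwise 'putative'."""
    for ref in reference:
        if candidate.mature_sequence == ref.mature_sequence:
            return "known"
        if (
            candidate.strand == ref.hairpin_interval.strand
            and overlap_length(candidate.hairpin_interval, ref.hairpin_interval) > 0
        ):
            return "known"
    return "putative"


class GenomicLocationClassifier:
    """Maps an interval to the highest-precedence overlapping feature class."""

    def __init__(self, genes: Sequence[GeneModel], strand_aware: bool = False) -> None:
        self.strand_aware = strand_aware
        self._index = GenomeIndex()
        for gene in genes:
            if gene.biotype == "protein_coding":
                for iv in gene.cds_union:
                    self._index.add(iv, ("coding", gene.strand, iv))
                for iv in gene.utr_union:
                    self._index.add(iv, ("utr", gene.strand, iv))
            elif gene.biotype == "lncRNA":
                for iv in gene.exon_union:
                    self._index.add(iv, ("lncRNA", gene.strand, iv))
            self._index.add(gene.span, ("intronic", gene.strand, gene.span))

    def classify(self, interval: GenomicInterval) -> str:
        best = len(LOCATION_LABELS) - 1  # intergenic
        for label, strand, iv in self._index.query(interval):
            if self.strand_aware and strand != interval.strand:
                continue
            if overlap_length(interval, iv) > 0:
                best = min(best, LOCATION_LABELS.index(label))
        return LOCATION_LABELS[best]


def classify_genomic_location(
    mature_interval: GenomicInterval,
    genes: Sequence[GeneModel],
    strand_aware: bool = False,
) -> str:
    return GenomicLocationClassifier(genes, strand_aware).classify(mature_interval)


def build_catalog(
    candidates: Sequence[MiRNACandidate],
    reference: Sequence[ReferenceMiRNA],
    genes: Sequence[GeneModel],
    min_score: float = 1.0,
    min_reads: int = 20,
    strand_aware_location: bool = False,
) -> list[CatalogEntry]:
    """Filter then annotate candidates with status and genomic location."""
    clf = GenomicLocationClassifier(genes, strand_aware_location)
    retained = filter_candidates(candidates, min_score, min_reads)
    return [
        CatalogEntry(
            candidate=c,
            status=classify_known_putative(c, reference),
            location=clf.classify(c.mature_interval),
        )
        for c in retained
    ]


def summarize_catalog(
    entries: Sequence[CatalogEntry], sample_ids: Sequence[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Summary tables of a built catalog.

    Returns
    -------
    dict with:
      ``location_pct`` — location percentage per status (rows sum to 100);
      ``top10_read_pct`` — per-sample read percentages of the ten miRNAs
      with the highest mean percentage, where each sample's denominator
      is the total mature reads of *known* entries in that sample;
      ``status_counts`` — number of known / putative entries.
    """
    if not entries:
        return {
            "location_pct": pd.DataFrame(),
            "top10_read_pct": pd.DataFrame(),
            "status_counts": pd.DataFrame(),
        }
    n_samples = len(entries[0].candidate.read_counts)
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n_samples)]

    rows = pd.DataFrame(
        {
            "id": [e.candidate.candidate_id for e in entries],
            "status": [e.status for e in entries],
            "location": [e.location for e in entries],
        }
    )
    loc = (
        rows.groupby(["status", "location"]).size().unstack(fill_value=0)
        .reindex(columns=list(LOCATION_LABELS), fill_value=0)
    )
    location_pct = 100 * loc.div(loc.sum(axis=1), axis=0)

    counts = pd.DataFrame(
        [e.candidate.read_counts for e in entries],
        index=rows["id"],
        columns=list(sample_ids),
        dtype=float,
    )
    known_totals = counts[rows.set_index("id")["status"] == "known"].sum(axis=0)
    known_totals = known_totals.replace(0, pd.NA)
    read_pct = 100 * counts.div(known_totals, axis=1)
    top10 = read_pct.loc[read_pct.mean(axis=1).sort_values(ascending=False).index[:10]]

    status_counts = rows["status"].value_counts().rename("n").to_frame()
    return {
        "location_pct": location_pct,
        "top10_read_pct": top10,
        "status_counts": status_counts,
    }


CANDIDATE_COLUMNS = [
    "id", "score", "chrom", "hp_start", "hp_end", "strand",
    "mat_start", "mat_end", "arm", "sequence",
]


def write_candidates(
    candidates: Sequence[MiRNACandidate], path, sample_ids: Sequence[str]
) -> None:
    rows = []
    for c in candidates:
        rows.append(
            [
                c.candidate_id, c.score,
                c.hairpin_interval.chrom, c.hairpin_interval.start, c.hairpin_interval.end,
                c.strand, c.mature_interval.start, c.mature_interval.end,
                c.arm, c.mature_sequence, *c.read_counts,
            ]
        )
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS + list(sample_ids)).to_csv(
        path, sep="\t", index=False
    )


def read_candidates(path) -> tuple[list[MiRNACandidate], list[str]]:
    frame = pd.read_csv(path, sep="\t")
    sample_ids = [c for c in frame.columns if c not in CANDIDATE_COLUMNS]
    candidates = []
    for row in frame.itertuples(index=False):
        hairpin = GenomicInterval(row.chrom, int(row.hp_start), int(row.hp_end), row.strand)
        mature = GenomicInterval(row.chrom, int(row.mat_start), int(row.mat_end), row.strand)
        candidates.append(
            MiRNACandidate(
                candidate_id=str(row.id),
                score=float(row.score),
                hairpin_interval=hairpin,
                mature_interval=mature,
                arm=str(row.arm),
                mature_sequence=str(row.sequence),
                read_counts=tuple(int(getattr(row, s)) for s in sample_ids),
            )
        )
    return candidates, sample_ids
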