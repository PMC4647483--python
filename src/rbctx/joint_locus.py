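"""Co-expression loci: expressed long RNAs spanning pre-miRNA hairpins.

Anucleate erythrocytes retain both a long RNA and the mature miRNAs of a
hairpin at a handful of loci, in two geometries: a transcript spanning
the entire hairpin plus flanking sequence (FULL_SPAN), or a short
transcript covering only the strand-aware 5' portion of the hairpin
(FIVE_PRIME_ONLY — the miR-4732-like arrangement next to the miR-144/451
cluster).  A locus is reported only when a retained mature miRNA maps
inside the hairpin and the transcript's aggregated read support strictly
exceeds a coverage floor (default 50 reads).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genome_model import GenomicInterval, PreMiRNALocus, overlap_length
from .mirna_catalog import MiRNACandidate

__all__ = [
    "LongTranscriptCall",
    "CoExpressionLocus",
    "PATTERNS",
    "find_spanning_transcripts",
    "classify_span_pattern",
    "transcript_support",
    "call_coexpression_loci",
    "render_locus_report",
    "read_locus_report",
]

PATTERNS = ("FULL_SPAN", "FIVE_PRIME_ONLY", "PARTIAL_OTHER")


@dataclass(frozen=True)
class LongTranscriptCall:
    """An expressed long-RNA interval with per-sample read support."""

    transcript_id: str
    interval: GenomicInterval
    support: tuple[int, ...]  # reads overlapping the interval, per sample

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.support):
            raise ValueError(f"{self.transcript_id}: negative read support")

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class CoExpressionLocus:
    locus_id: str
    transcript_id: str
    pattern: str
    locus_coverage: float
    mirna_expressed: bool


def transcript_support(
    interval: GenomicInterval, reads: Mapping[str, Sequence[GenomicInterval]]
) -> tuple[int, ...]:
    """Per-sample count of read placements overlapping the interval by >= 1 base."""
    return tuple(
        sum(overlap_length(interval, r) > 0 for r in placements)
        for placements in reads.values()
    )


def find_spanning_transcripts(
    transcripts: Sequence[LongTranscriptCall],
    loci: Sequence[PreMiRNALocus],
    same_strand: bool = True,
) -> list[tuple[LongTranscriptCall, PreMiRNALocus]]:
    """All (transcript, hairpin) pairs overlapping by >= 1 base.

    With ``same_strand`` (the default) only pairs on one strand are kept —
    an antisense transcript over a hairpin is a different phenomenon.
    """
    pairs = []
    for tx in transcripts:
        for locus in loci:
            if same_strand and tx.strand != locus.strand:
                continue
            if overlap_length(tx.interval, locus.hairpin) > 0:
                pairs.append((tx, locus))
    return pairs


def classify_span_pattern(
    transcript_interval: GenomicInterval, locus: PreMiRNALocus, flank: int = 10
) -> str:
    """FULL_SPAN, FIVE_PRIME_ONLY, or PARTIAL_OTHER for one overlapping pair.

    FULL_SPAN: the transcript covers the hairpin extended by ``flank`` nt
    on both genomic sides.  FIVE_PRIME_ONLY: >= 1 base of the strand-aware
    5p arm and 0 bases of the 3p arm.  Anything else is PARTIAL_OTHER.
    """
    if overlap_length(transcript_interval, locus.hairpin) == 0:
        raise ValueError("transcript does not overlap the hairpin")
    flanked = GenomicInterval(
        locus.hairpin.chrom,
        max(0, locus.hairpin.start - flank),
        locus.hairpin.end + flank,
        locus.hairpin.strand,
    )
    if transcript_interval.contains(flanked):
        return "FULL_SPAN"
    if (
        overlap_length(transcript_interval, locus.arm5p) > 0
        and overlap_length(transcript_interval, locus.arm3p) == 0
    ):
        return "FIVE_PRIME_ONLY"
    return "PARTIAL_OTHER"


def _aggregate(support: tuple[int, ...], mode: str) -> float:
    if not support:
        return 0.0
    if mode == "mean":
        return sum(support) / len(support)
    if mode == "min":
        return float(min(support))
    if mode == "sum":
        return float(sum(support))
    raise ValueError(f"aggregation must be mean|min|sum, got {mode!r}")


def call_coexpression_loci(
    pairs: Sequence[tuple[LongTranscriptCall, PreMiRNALocus]],
    retained_mirnas: Sequence[MiRNACandidate],
    coverage_min: float = 50.0,
    aggregation: str = "mean",
    flank: int = 10,
    include_partial: bool = False,
) -> list[CoExpressionLocus]:
    """Report loci with an expressed miRNA and coverage strictly above the floor.

    ``retained_mirnas`` are the candidates surviving the catalog filter; a
    locus has an expressed miRNA when one of them maps inside the hairpin
    on the same strand.  Coverage is the transcript's per-sample support
    aggregated by ``aggregation`` and must be > ``coverage_min`` (strict).
    """
    out = []
    for tx, locus in pairs:
        expressed = any(
            locus.hairpin.contains(c.mature_interval) and c.strand == locus.strand
            for c in retained_mirnas
        )
        coverage = _aggregate(tx.support, aggregation)
        pattern = classify_span_pattern(tx.interval, locus, flank)
        if not expressed:
            continue
        if coverage <= coverage_min:
            continue
        if pattern == "PARTIAL_OTHER" and not include_partial:
            continue
        out.append(
            CoExpressionLocus(
                locus_id=locus.locus_id,
                transcript_id=tx.transcript_id,
                pattern=pattern,
                locus_coverage=coverage,
                mirna_expressed=True,
            )
        )
    return sorted(out, key=lambda c: (-c.locus_coverage, c.locus_id))


def render_locus_report(
    calls: Sequence[CoExpressionLocus],
    transcripts: Sequence[LongTranscriptCall],
    loci: Sequence[PreMiRNALocus],
    window: int = 10_000,
) -> pd.DataFrame:
    """Per-call element table: the transcript plus every hairpin nearby.

    A hairpin belongs to a call's neighbourhood when it lies within
    ``window`` nt of the transcript interval on the same chromosome, so a
    clustered arrangement (several hairpins within a few kb, as in the
    miR-144/451 cluster) is reported as one multi-element locus.  Columns
    are fixed: element positions, length, strand, pattern (transcripts
    only) and per-sample support (semicolon-joined for transcripts).
    """
    tx_by_id = {t.transcript_id: t for t in transcripts}
    rows = []
    for call in calls:
        tx = tx_by_id[call.transcript_id]
        near = GenomicInterval(
            tx.interval.chrom,
            max(0, tx.interval.start - window),
            tx.interval.end + window,
            tx.interval.strand,
        )
        for locus in loci:
            if overlap_length(near, locus.hairpin) > 0:
                rows.append(
                    {
                        "call_locus": call.locus_id,
                        "element_id": locus.locus_id,
                        "element_type": "pre_mirna",
                        "chrom": locus.hairpin.chrom,
                        "start": locus.hairpin.start,
                        "end": locus.hairpin.end,
                        "strand": locus.strand,
                        "length": locus.hairpin.length,
                        "pattern": "",
                        "support": "",
                    }
                )
        rows.append(
            {
                "call_locus": call.locus_id,
                "element_id": tx.transcript_id,
                "element_type": "transcript",
                "chrom": tx.interval.chrom,
                "start": tx.interval.start,
                "end": tx.interval.end,
                "strand": tx.strand,
                "length": tx.interval.length,
                "pattern": call.pattern,
                "support": ";".join(str(s) for s in tx.support),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "call_locus", "element_id", "element_type", "chrom",
            "start", "end", "strand", "length", "pattern", "support",
        ],
    )
    return frame.sort_values(
        ["call_locus", "chrom", "start", "element_id"], kind="mergesort"
    ).reset_index(drop=True)


def read_locus_report(path) -> pd.DataFrame:
    """Read a report written with ``DataFrame.to_csv(sep='\\t', index=False)``."""
    frame = pd.read_csv(path, sep="\t", dtype={"pattern": str, "support": str})
    frame["pattern"] = frame["pattern"].fillna("")
    frame["support"] = frame["support"].fillna("")
    return frame
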