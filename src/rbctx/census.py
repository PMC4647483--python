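"""Long-RNA expression census: RPKM, expressed-gene calling, read
genomic-location distribution, and top-N ranking.

The census asks, for an anucleate cell type that cannot transcribe,
which transcripts persist at appreciable levels.  A gene is called
*expressed* when its RPKM (reads per kilobase of exon model per million
mapped reads) reaches an inclusive threshold, 0.5 by default, in at
least one sample (``mode="any"``) or in every sample (``mode="all"``).

Reads are also assigned to genomic compartments — exonic, intronic,
proximal-intergenic (within a window of a TSS/TES), distal-intergenic —
with the precedence exonic > intronic > proximal > distal.  A read is
exonic when at least half of its bases fall in the exon union of some
gene; intronic when it touches a gene body without being exonic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomeIndex, GenomicInterval, overlap_length

__all__ = [
    "ExpressionMatrix",
    "CensusResult",
    "LocationDistribution",
    "compute_rpkm",
    "call_expressed",
    "run_census",
    "ReadLocationClassifier",
    "read_location_distribution",
    "top_n_by_mean",
    "load_top25_table",
    "LOCATION_CATEGORIES",
]

LOCATION_CATEGORIES = ("exonic", "intronic", "proximal_intergenic", "distal_intergenic")


@dataclass
class ExpressionMatrix:
    """Raw counts (genes x samples) with exonic lengths and library sizes.

    ``library_size`` is the total number of mapped reads per sample; it
    need not equal the column sum of counts (reads mapped outside genes
    still count toward the library).
    """

    counts: pd.DataFrame
    exonic_length: pd.Series
    library_size: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.exonic_length = self.exonic_length.reindex(self.counts.index)
        self.library_size = self.library_size.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        if self.exonic_length.isna().any() or (self.exonic_length < 1).any():
            raise ValueError("every gene needs an exonic_length >= 1")
        if self.library_size.isna().any():
            raise ValueError("every sample needs a library size")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


def compute_rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """RPKM(g, s) = 1e9 * counts(g, s) / (exonic_length(g) * library_size(s))."""
    lib = matrix.library_size.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("library size must be positive for RPKM")
    length = matrix.exonic_length.to_numpy(dtype=float)
    values = 1e9 * matrix.counts.to_numpy() / (length[:, None] * lib[None, :])
    return pd.DataFrame(values, index=matrix.gene_ids, columns=matrix.sample_ids)


def call_expressed(
    rpkm: pd.DataFrame, threshold: float = 0.5, mode: str = "any"
) -> set[str]:
    """Genes with RPKM >= threshold in at least one (any) or every (all) sample.

    The boundary is inclusive: a gene sitting exactly at the threshold is
    expressed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    if rpkm.empty:
        return set()
    hit = rpkm >= threshold
    mask = hit.any(axis=1) if mode == "any" else hit.all(axis=1)
    return set(rpkm.index[mask])


@dataclass
class CensusResult:
    rpkm: pd.DataFrame
    expressed_any: set[str]
    expressed_all: set[str]
    per_sample_expressed: pd.Series  # genes at/above threshold per sample
    threshold: float

    def __post_init__(self) -> None:
        assert self.expressed_all <= self.expressed_any


def run_census(matrix: ExpressionMatrix, threshold: float = 0.5) -> CensusResult:
    rpkm = compute_rpkm(matrix)
    return CensusResult(
        rpkm=rpkm,
        expressed_any=call_expressed(rpkm, threshold, "any"),
        expressed_all=call_expressed(rpkm, threshold, "all"),
        per_sample_expressed=(rpkm >= threshold).sum(axis=0),
        threshold=threshold,
    )


class ReadLocationClassifier:
    """Assigns one compartment per read with fixed precedence.

    Parameters
    ----------
    genes:
        Annotation to classify against.
    proximal_window:
        Width in nt of the strand-aware upstream-of-TSS / downstream-of-TES
        zones that define the proximal-intergenic compartment (default
        10 kb).
    exonic_min_fraction:
        Minimum fraction of read bases overlapping one gene's exon union
        for the exonic call (default 0.5, a majority rule).
    strand_aware:
        When True only genes on the read's strand are considered.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        proximal_window: int = 10_000,
        exonic_min_fraction: float = 0.5,
        strand_aware: bool = False,
    ) -> None:
        self.proximal_window = proximal_window
        self.exonic_min_fraction = exonic_min_fraction
        self.strand_aware = strand_aware
        self._exon_index = GenomeIndex()
        self._body_index = GenomeIndex()
        self._proximal_index = GenomeIndex()
        for gene in genes:
            for iv in gene.exon_union:
                self._exon_index.add(iv, (gene.gene_id, gene.strand, iv))
            body = gene.span
            self._body_index.add(body, (gene.gene_id, gene.strand, body))
            for zone in self._proximal_zones(gene):
                self._proximal_index.add(zone, (gene.gene_id, gene.strand, zone))

    def _proximal_zones(self, gene: GeneModel) -> list[GenomicInterval]:
        w = self.proximal_window
        body = gene.span
        zones = []
        if gene.strand == "+":
            candidates = [(body.start - w, body.start), (body.end, body.end + w)]
        else:
            candidates = [(body.end, body.end + w), (body.start - w, body.start)]
        for start, end in candidates:
            start = max(0, start)
            if start < end:
                zones.append(GenomicInterval(body.chrom, start, end, gene.strand))
        return zones

    def _strand_ok(self, read: GenomicInterval, feature_strand: str) -> bool:
        return not self.strand_aware or read.strand == feature_strand

    def classify(self, read: GenomicInterval) -> str:
        # exonic: >= exonic_min_fraction of read bases in one gene's exon union
        per_gene: dict[str, int] = {}
        for gene_id, strand, iv in self._exon_index.query(read):
            if self._strand_ok(read, strand):
                per_gene[gene_id] = per_gene.get(gene_id, 0) + overlap_length(read, iv)
        if per_gene and max(per_gene.values()) >= self.exonic_min_fraction * read.length:
            return "exonic"
        for _gene_id, strand, iv in self._body_index.query(read):
            if self._strand_ok(read, strand) and overlap_length(read, iv) > 0:
                return "intronic"
        for _gene_id, strand, iv in self._proximal_index.query(read):
            if self._strand_ok(read, strand) and overlap_length(read, iv) > 0:
                return "proximal_intergenic"
        return "distal_intergenic"


@dataclass
class LocationDistribution:
    """Per-sample compartment counts and fractions, plus their average."""

    counts: pd.DataFrame  # categories x samples
    fractions: pd.DataFrame  # categories x samples, columns sum to 1

    @property
    def mean_fractions(self) -> pd.Series:
        return self.fractions.mean(axis=1)

    def three_category(self, merge_proximal_with: str = "intronic") -> pd.DataFrame:
        """Collapse to exonic / intronic / intergenic.

        The proximal-intergenic compartment is ambiguous in a three-way
        report; by default it is merged into the intronic (gene-associated)
        tally, with ``merge_proximal_with="intergenic"`` as the alternative
        reading.
        """
        if merge_proximal_with not in ("intronic", "intergenic"):
            raise ValueError("merge_proximal_with must be 'intronic' or 'intergenic'")
        out = pd.DataFrame(
            {
                "exonic": self.counts.loc["exonic"],
                "intronic": self.counts.loc["intronic"],
                "intergenic": self.counts.loc["distal_intergenic"],
            }
        ).T
        out.loc[merge_proximal_with] += self.counts.loc["proximal_intergenic"]
        return out / out.sum(axis=0)


def read_location_distribution(
    reads: Mapping[str, Sequence[GenomicInterval]],
    genes: Sequence[GeneModel],
    proximal_window: int = 10_000,
    exonic_min_fraction: float = 0.5,
    strand_aware: bool = False,
) -> LocationDistribution:
    """Compartment distribution of read placements, per sample and averaged."""
    clf = ReadLocationClassifier(genes, proximal_window, exonic_min_fraction, strand_aware)
    counts = pd.DataFrame(
        0, index=list(LOCATION_CATEGORIES), columns=list(reads.keys()), dtype=int
    )
    for sample, placements in reads.items():
        for read in placements:
            counts.loc[clf.classify(read), sample] += 1
    totals = counts.sum(axis=0).replace(0, np.nan)
    fractions = (counts / totals).fillna(0.0)
    return LocationDistribution(counts=counts, fractions=fractions)


def top_n_by_mean(expression: pd.DataFrame | pd.Series, n: int) -> pd.DataFrame:
    """Top-n genes by mean expression, descending; ties broken by gene id.

    Accepts a genes x samples frame (mean over samples) or a per-gene
    summary series.  Returns a frame with columns rank, gene, value,
    rank 1 being the largest.  Asking for more rows than exist returns
    the whole table with a warning.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    values = expression.mean(axis=1) if isinstance(expression, pd.DataFrame) else expression
    if n > len(values):
        warnings.warn(
            f"requested top {n} of {len(values)} genes; returning all", stacklevel=2
        )
        n = len(values)
    frame = values.rename("value").rename_axis("gene").reset_index()
    frame = frame.sort_values(["value", "gene"], ascending=[False, True], kind="mergesort")
    frame = frame.head(n).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


def load_top25_table() -> pd.DataFrame:
    """The packaged table of the 25 most abundant erythrocyte long RNAs.

    Columns: gene, description, value (average relative expression, as
    published; the normalisation of the published column is not
    RPKM-calibrated, so the values are kept verbatim).
    """
    with resources.files("rbctx.data").joinpath(
        "top25_erythrocyte_long_rnas.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
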