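"""Synthetic genomes, reads, miRNA candidates, and ortholog sets with
planted truth.

The generator fabricates inputs with the statistical shape of an
erythrocyte long+short RNA sequencing study — a toy annotated genome,
read placements distributed over exon/intron/proximal/distal
compartments, miRDeep-style candidate records straddling the retention
thresholds, six-species ortholog regions with controlled seed/non-seed
mismatches, and long transcripts spanning pre-miRNA hairpins in both
co-expression geometries — while recording the truth of every planted
entity so downstream modules can be scored against it.

Everything is deterministic under a fixed seed: each generator derives
its own random stream from ``(seed, stage)`` so regenerating any one
output is byte-identical regardless of which other generators ran.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import ExpressionMatrix
from .conservation import DEFAULT_PANEL, SpeciesSequenceSet, seed_positions
from .genome_model import (
    GeneModel,
    GenomicInterval,
    PreMiRNALocus,
    ReferenceMiRNA,
    Transcript,
)
from .joint_locus import LongTranscriptCall
from .mirna_catalog import MiRNACandidate

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "SyntheticGenome",
    "CapacityError",
    "ConfigurationError",
    "generate_genome",
    "simulate_reads",
    "simulate_mirna_candidates",
    "generate_ortholog_set",
    "simulate_conservation_cohort",
    "simulate_coexpression",
    "candidate_grid",
]

RNA_BASES = np.array(list("ACGU"))


class CapacityError(ValueError):
    """The requested features do not fit in the configured genome."""


class ConfigurationError(ValueError):
    """A config value is inconsistent with the requested simulation."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with defaults matching the study design.

    Sample counts mirror the sequencing cohorts (3 long-RNA erythrocyte
    samples, 5 short-RNA samples); the compartment fractions default to a
    strongly exonic profile like a mature-erythrocyte library.  The
    expression model separates expressed genes (log-normal relative
    abundance) from unexpressed genes (a Poisson background at one tenth
    of the count equivalent of the RPKM-0.5 expression floor).
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 4_500_000
    n_genes: int = 200
    biotype_proportions: tuple[float, float, float] = (0.7, 0.2, 0.1)  # coding/lnc/other
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (100, 400)
    intron_length: tuple[int, int] = (200, 2_000)
    intergenic_gap: tuple[int, int] = (25_000, 40_000)
    # pre-miRNA loci
    n_pre_mirna_loci: int = 14
    pre_mirna_intronic_fraction: float = 0.5
    n_mir_cluster_loci: int = 1  # 3-hairpin clusters within a 6 kb window
    # long-RNA assay
    n_samples: int = 3
    reads_per_sample: int = 10_000
    read_length: int = 50
    compartment_fractions: tuple[float, float, float, float] = (0.93, 0.04, 0.02, 0.01)
    expressed_fraction: float = 0.5
    expression_lognormal: tuple[float, float] = (3.0, 1.0)  # mu, sigma
    rpkm_floor: float = 0.5  # background mean = floor-equivalent counts / 10
    # short-RNA assay
    n_short_samples: int = 5
    n_known_mirnas: int = 6
    n_putative_mirnas: int = 4
    n_fail_score: int = 2
    n_fail_reads: int = 2
    score_lognormal: tuple[float, float] = (1.0, 0.8)
    mature_reads_nbinom: tuple[float, float] = (2.0, 200.0)  # dispersion n, mean
    # conservation
    ortholog_flank: int = 30
    # co-expression: (pattern, per-sample coverage, miRNA expressed at locus)
    planted_coexpression: tuple[tuple[str, int, bool], ...] = (
        ("FULL_SPAN", 120, True),
        ("FIVE_PRIME_ONLY", 80, True),
        ("FULL_SPAN", 50, True),   # decoy: exactly at the strict coverage floor
        ("FULL_SPAN", 120, False), # decoy: miRNA below the retention thresholds
    )
    coexpression_flank: int = 10

    def validate(self) -> list[str]:
        problems = []
        if abs(sum(self.compartment_fractions) - 1.0) > 1e-9:
            problems.append("compartment_fractions must sum to 1")
        if any(f < 0 for f in self.compartment_fractions):
            problems.append("compartment_fractions must be non-negative")
        if abs(sum(self.biotype_proportions) - 1.0) > 1e-9:
            problems.append("biotype_proportions must sum to 1")
        for name in ("n_chroms", "chrom_length", "n_samples", "reads_per_sample",
                     "read_length", "n_short_samples"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.n_genes < 0 or self.n_pre_mirna_loci < 0:
            problems.append("feature counts must be non-negative")
        if not 0 <= self.expressed_fraction <= 1:
            problems.append("expressed_fraction must be in [0, 1]")
        if not 0 <= self.pre_mirna_intronic_fraction <= 1:
            problems.append("pre_mirna_intronic_fraction must be in [0, 1]")
        return problems


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


@dataclass
class PlantedTruth:
    """Ground truth for every simulated entity, keyed by identifier."""

    gene_expressed: dict[str, bool] = field(default_factory=dict)
    expression_level: dict[str, float] = field(default_factory=dict)
    pre_mirna_location: dict[str, str] = field(default_factory=dict)  # intronic|intergenic
    cluster_loci: list[tuple[str, ...]] = field(default_factory=list)
    read_compartment: dict[str, str] = field(default_factory=dict)
    candidate_truth: pd.DataFrame | None = None
    conservation_species: dict[str, frozenset[str]] = field(default_factory=dict)
    coexpression: pd.DataFrame | None = None


@dataclass
class SyntheticGenome:
    genes: list[GeneModel]
    pre_mirna_loci: list[PreMiRNALocus]
    reference_mirnas: list[ReferenceMiRNA]
    truth: PlantedTruth
    config: SimulationConfig


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA_BASES, size=length))


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    biotype: str,
    config: SimulationConfig,
) -> GeneModel:
    n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length
        if i < n_exons - 1:
            pos += int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
    cds: tuple[GenomicInterval, ...] = ()
    if biotype == "protein_coding":
        # UTRs: trim 60 nt off the first and last exon, CDS covers the rest
        trimmed = []
        for i, e in enumerate(exons):
            s, t = e.start, e.end
            if i == 0:
                s = min(s + 60, t - 1)
            if i == len(exons) - 1:
                t = max(t - 60, s + 1)
            if s < t:
                trimmed.append(GenomicInterval(chrom, s, t, strand))
        cds = tuple(trimmed)
    tx = Transcript(transcript_id=f"{gene_id}.t1", exons=tuple(exons), cds=cds)
    return GeneModel(gene_id=gene_id, biotype=biotype, transcripts=(tx,))


def _make_hairpin(
    rng: np.random.Generator, locus_id: str, chrom: str, start: int, strand: str
) -> PreMiRNALocus:
    arm = 22
    loop = int(rng.integers(14, 31))
    a = GenomicInterval(chrom, start, start + arm, strand)
    b = GenomicInterval(chrom, start + arm, start + arm + loop, strand)
    c = GenomicInterval(chrom, start + arm + loop, start + 2 * arm + loop, strand)
    hairpin = GenomicInterval(chrom, start, start + 2 * arm + loop, strand)
    if strand == "+":
        arm5p, arm3p = a, c
    else:
        arm5p, arm3p = c, a  # 5p arm sits at the larger coordinates on '-'
    return PreMiRNALocus(locus_id=locus_id, hairpin=hairpin, arm5p=arm5p, loop=b, arm3p=arm3p)


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Toy genome: non-overlapping genes, pre-miRNA loci, reference miRNAs.

    Genes are laid down left to right with wide intergenic gaps so that
    distal intergenic space (beyond the 10 kb proximal windows) always
    exists.  Pre-miRNA loci are placed intronically (inside host-gene
    introns, host strand) or intergenically per the configured fraction;
    one or more 3-hairpin clusters within a 6 kb window emulate a
    miR-144/451-like arrangement.  Reference miRNAs are minted from the
    first ``n_known_mirnas`` loci.
    """
    problems = config.validate()
    if problems:
        raise ConfigurationError("; ".join(problems))
    rng = _rng(config, stage=1)
    truth = PlantedTruth()

    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genes: list[GeneModel] = []
    cursors = {c: int(rng.integers(30_000, 60_000)) for c in chroms}
    biotype_draw = rng.choice(
        ["protein_coding", "lncRNA", "other_ncRNA"],
        size=config.n_genes,
        p=list(config.biotype_proportions),
    )
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        gene = _make_gene(rng, f"G{i + 1:04d}", chrom, cursors[chrom], str(biotype_draw[i]), config)
        if gene.span.end > config.chrom_length - 30_000:
            raise CapacityError(
                f"chromosome {chrom} too short for {config.n_genes} genes: "
                f"increase chrom_length or reduce n_genes"
            )
        genes.append(gene)
        cursors[chrom] = gene.span.end + int(
            rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1)
        )

    # pre-miRNA loci
    loci: list[PreMiRNALocus] = []
    intronic_hosts = [g for g in genes if any(iv.length >= 120 for iv in g.introns)]
    n_intronic = round(config.n_pre_mirna_loci * config.pre_mirna_intronic_fraction)
    for j in range(config.n_pre_mirna_loci):
        locus_id = f"mir{j + 1:03d}"
        if j < n_intronic:
            if not intronic_hosts:
                raise CapacityError("no gene has an intron wide enough for a hairpin")
            host = intronic_hosts[int(rng.integers(len(intronic_hosts)))]
            intron = max(host.introns, key=lambda iv: iv.length)
            start = int(rng.integers(intron.start + 5, intron.end - 115))
            loci.append(_make_hairpin(rng, locus_id, host.chrom, start, host.strand))
            truth.pre_mirna_location[locus_id] = "intronic"
        else:
            chrom = chroms[j % len(chroms)]
            start = _intergenic_start(rng, genes, chrom, config, width=120)
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append(_make_hairpin(rng, locus_id, chrom, start, strand))
            truth.pre_mirna_location[locus_id] = "intergenic"

    # miR-144/451-like clusters: three hairpins within a 6 kb window, one strand
    for k in range(config.n_mir_cluster_loci):
        chrom = chroms[k % len(chroms)]
        base = _intergenic_start(rng, genes, chrom, config, width=6_000)
        strand = "+" if rng.random() < 0.5 else "-"
        ids = []
        offset = 0
        for m in range(3):
            locus_id = f"cluster{k + 1}_mir{m + 1}"
            loci.append(_make_hairpin(rng, locus_id, chrom, base + offset, strand))
            truth.pre_mirna_location[locus_id] = "intergenic"
            ids.append(locus_id)
            offset += int(rng.integers(1_200, 2_400))
        truth.cluster_loci.append(tuple(ids))

    # reference miRNAs from the first n_known loci (mature = 5p arm)
    reference: list[ReferenceMiRNA] = []
    if config.n_known_mirnas > len(loci):
        raise CapacityError("n_known_mirnas exceeds the number of pre-miRNA loci")
    for locus in loci[: config.n_known_mirnas]:
        reference.append(
            ReferenceMiRNA(
                mir_id=f"ref-{locus.locus_id}",
                mature_sequence=_random_rna(rng, 22),
                mature_interval=locus.arm5p,
                hairpin_interval=locus.hairpin,
            )
        )
    return SyntheticGenome(
        genes=genes, pre_mirna_loci=loci, reference_mirnas=reference,
        truth=truth, config=config,
    )


def _intergenic_start(
    rng: np.random.Generator,
    genes: Sequence[GeneModel],
    chrom: str,
    config: SimulationConfig,
    width: int,
    clearance: int = 11_000,
) -> int:
    """A start position at least ``clearance`` nt away from every gene body."""
    bodies = sorted(
        (g.span.start, g.span.end) for g in genes if g.chrom == chrom
    )
    gaps = []
    prev_end = 1_000
    for start, end in bodies + [(config.chrom_length - 1_000, config.chrom_length)]:
        lo, hi = prev_end + clearance, start - clearance - width
        if hi > lo:
            gaps.append((lo, hi))
        prev_end = max(prev_end, end)
    if not gaps:
        raise CapacityError(f"no intergenic gap of width {width} on {chrom}")
    lo, hi = gaps[int(rng.integers(len(gaps)))]
    return int(rng.integers(lo, hi))


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _compartment_pools(
    genome: SyntheticGenome, window: int = 10_000
) -> dict[str, list[GenomicInterval]]:
    """Placement regions per compartment, mirroring the classifier geometry."""
    from .genome_model import merge_intervals, subtract_intervals

    config = genome.config
    read_len = config.read_length
    bodies = [g.span for g in genome.genes]
    introns = [iv for g in genome.genes for iv in g.introns if iv.length >= read_len]
    proximal_raw = []
    for g in genome.genes:
        body = g.span
        proximal_raw.append(
            GenomicInterval(body.chrom, max(0, body.start - window), body.start, g.strand)
        )
        proximal_raw.append(
            GenomicInterval(body.chrom, body.end, body.end + window, g.strand)
        )
    proximal = [
        iv for iv in subtract_intervals(proximal_raw, bodies) if iv.length >= read_len
    ]
    near = merge_intervals(
        [
            GenomicInterval(b.chrom, max(0, b.start - window - 50), b.end + window + 50, b.strand)
            for b in bodies
        ]
    )
    whole = [
        GenomicInterval(f"chr{i + 1}", 1_000, config.chrom_length - 1_000)
        for i in range(config.n_chroms)
    ]
    distal = [iv for iv in subtract_intervals(whole, near) if iv.length >= read_len]
    return {
        "intronic": introns,
        "proximal_intergenic": proximal,
        "distal_intergenic": distal,
    }


def _place_in(
    rng: np.random.Generator, pool: Sequence[GenomicInterval], read_len: int, strand: str
) -> GenomicInterval:
    lengths = np.array([iv.length - read_len + 1 for iv in pool], dtype=float)
    iv = pool[int(rng.choice(len(pool), p=lengths / lengths.sum()))]
    start = int(rng.integers(iv.start, iv.end - read_len + 1))
    return GenomicInterval(iv.chrom, start, start + read_len, strand)


def simulate_reads(
    genome: SyntheticGenome,
    config: SimulationConfig | None = None,
    expression_override: Mapping[str, float] | None = None,
    sample_prefix: str = "RBC",
) -> tuple[dict[str, list[tuple[GenomicInterval, str]]], ExpressionMatrix, PlantedTruth]:
    """Place reads by compartment and aggregate per-gene counts.

    Each read draws a compartment from the multinomial over
    ``compartment_fractions`` and is placed uniformly within a feature of
    that compartment; exonic reads choose a gene in proportion to its
    planted expression level.  Unexpressed genes additionally receive a
    Poisson background at one tenth of the count equivalent of the
    RPKM-0.5 floor.  The truth compartment of a read is its placement
    origin.  Library size is the total number of placed reads per sample.
    """
    config = config or genome.config
    rng = _rng(config, stage=2)
    truth = genome.truth
    read_len = config.read_length

    # planted expression status and levels (drawn once per genome)
    if not truth.gene_expressed:
        mu, sigma = config.expression_lognormal
        for g in genome.genes:
            expressed = rng.random() < config.expressed_fraction
            truth.gene_expressed[g.gene_id] = expressed
            truth.expression_level[g.gene_id] = (
                float(rng.lognormal(mu, sigma)) if expressed else 0.0
            )
    levels = expression_override or truth.expression_level

    pools = _compartment_pools(genome)
    for name, frac in zip(("intronic", "proximal_intergenic", "distal_intergenic"),
                          config.compartment_fractions[1:]):
        if frac > 0 and not pools[name]:
            raise ConfigurationError(
                f"compartment {name} has fraction {frac} but no placement features"
            )
    expressed_genes = [g for g in genome.genes if levels.get(g.gene_id, 0.0) > 0]
    if config.compartment_fractions[0] > 0 and not expressed_genes:
        raise ConfigurationError("exonic fraction > 0 but no expressed genes")
    gene_w = np.array([levels[g.gene_id] for g in expressed_genes], dtype=float)
    gene_p = gene_w / gene_w.sum()

    samples = [f"{sample_prefix}{i + 1}" for i in range(config.n_samples)]
    reads: dict[str, list[tuple[GenomicInterval, str]]] = {s: [] for s in samples}
    counts = pd.DataFrame(
        0, index=[g.gene_id for g in genome.genes], columns=samples, dtype=int
    )
    lib = {}
    for sample in samples:
        n_by_comp = rng.multinomial(config.reads_per_sample, config.compartment_fractions)
        rid = 0
        # exonic reads, gene-weighted
        gene_idx = rng.choice(len(expressed_genes), size=n_by_comp[0], p=gene_p)
        for gi in gene_idx:
            gene = expressed_genes[gi]
            read = _place_in(rng, gene.exon_union, read_len, gene.strand)
            name = f"{sample}:r{rid}"
            rid += 1
            reads[sample].append((read, name))
            truth.read_compartment[name] = "exonic"
            counts.loc[gene.gene_id, sample] += 1
        # background reads on unexpressed genes
        for gene in genome.genes:
            if truth.gene_expressed.get(gene.gene_id, False):
                continue
            lam = (
                config.rpkm_floor * gene.exonic_length * config.reads_per_sample / 1e9
            ) / 10.0
            for _ in range(int(rng.poisson(lam))):
                read = _place_in(rng, gene.exon_union, read_len, gene.strand)
                name = f"{sample}:r{rid}"
                rid += 1
                reads[sample].append((read, name))
                truth.read_compartment[name] = "exonic"
                counts.loc[gene.gene_id, sample] += 1
        # non-exonic compartments
        for comp, n in zip(("intronic", "proximal_intergenic", "distal_intergenic"),
                           n_by_comp[1:]):
            for _ in range(n):
                strand = "+" if rng.random() < 0.5 else "-"
                read = _place_in(rng, pools[comp], read_len, strand)
                name = f"{sample}:r{rid}"
                rid += 1
                reads[sample].append((read, name))
                truth.read_compartment[name] = comp
        lib[sample] = len(reads[sample])

    matrix = ExpressionMatrix(
        counts=counts,
        exonic_length=pd.Series(
            {g.gene_id: g.exonic_length for g in genome.genes}, name="exonic_length"
        ),
        library_size=pd.Series(lib, name="library_size"),
    )
    return reads, matrix, truth


# ---------------------------------------------------------------------------
# miRNA candidates
# ---------------------------------------------------------------------------

def _draw_counts(
    rng: np.random.Generator, config: SimulationConfig, n_samples: int
) -> np.ndarray:
    disp, mean = config.mature_reads_nbinom
    p = disp / (disp + mean)
    return rng.negative_binomial(disp, p, size=n_samples)


def simulate_mirna_candidates(
    genome: SyntheticGenome, config: SimulationConfig | None = None
) -> tuple[list[MiRNACandidate], pd.DataFrame]:
    """miRDeep-like records at the genome's pre-miRNA loci, with truth.

    The first ``n_known_mirnas`` loci carry the reference sequence and
    locus (known candidates); the next ``n_putative_mirnas`` get novel
    sequences at unannotated loci.  ``n_fail_score`` of the candidates
    are planted below the score threshold and ``n_fail_reads`` below the
    read threshold in every sample.  The returned truth table records
    status, planted location, and the expected filter outcome.
    """
    config = config or genome.config
    rng = _rng(config, stage=3)
    n_total = config.n_known_mirnas + config.n_putative_mirnas
    if n_total > len(genome.pre_mirna_loci):
        raise CapacityError("not enough pre-miRNA loci for the requested candidates")
    if config.n_fail_score + config.n_fail_reads > n_total:
        raise ConfigurationError("more planted failures than candidates")

    fail_score_ids = set(range(config.n_fail_score))
    fail_read_ids = set(range(config.n_fail_score, config.n_fail_score + config.n_fail_reads))
    candidates: list[MiRNACandidate] = []
    rows = []
    for i in range(n_total):
        locus = genome.pre_mirna_loci[i]
        known = i < config.n_known_mirnas
        if known:
            ref = genome.reference_mirnas[i]
            sequence = ref.mature_sequence
            mature = ref.mature_interval
        else:
            sequence = _random_rna(rng, 22)
            mature = locus.arm5p
        mu, sigma = config.score_lognormal
        if i in fail_score_ids:
            score = round(float(rng.uniform(0.1, 0.99)), 3)
        else:
            score = round(max(1.0, float(rng.lognormal(mu, sigma))), 3)
        counts = _draw_counts(rng, config, config.n_short_samples)
        if i in fail_read_ids:
            counts = np.minimum(counts, 19)
        elif counts.max() < 20:
            counts[int(rng.integers(config.n_short_samples))] += 20
        mat22 = GenomicInterval(
            mature.chrom, mature.start, mature.start + 22, mature.strand
        )
        candidate = MiRNACandidate(
            candidate_id=f"cand-{locus.locus_id}",
            score=score,
            hairpin_interval=locus.hairpin,
            mature_interval=mat22,
            arm="5p",
            mature_sequence=sequence,
            read_counts=tuple(int(c) for c in counts),
        )
        candidates.append(candidate)
        rows.append(
            {
                "id": candidate.candidate_id,
                "status": "known" if known else "putative",
                "location": genome.truth.pre_mirna_location[locus.locus_id],
                "passes_filter": score >= 1.0 and candidate.max_reads >= 20,
            }
        )
    truth_table = pd.DataFrame(rows).set_index("id")
    genome.truth.candidate_truth = truth_table
    return candidates, truth_table


def candidate_grid(
    scores: Sequence[float] = (0.5, 1.0, 1.5),
    max_reads: Sequence[int] = (19, 20, 1000),
    replicates: int = 1,
    n_samples: int = 5,
    seed: int = 0,
) -> tuple[list[MiRNACandidate], pd.DataFrame]:
    """A factorial grid of candidates straddling both retention thresholds.

    Every (score, max-reads) combination appears ``replicates`` times;
    the planted maximum lands in one sample with smaller counts elsewhere.
    The truth table marks the expected filter outcome (score >= 1 and
    max reads >= 20).
    """
    rng = np.random.default_rng(seed)
    candidates, rows = [], []
    i = 0
    for _ in range(replicates):
        for score in scores:
            for mx in max_reads:
                chrom = "chrS"
                start = 1_000 + i * 500
                hairpin = GenomicInterval(chrom, start, start + 66, "+")
                mature = GenomicInterval(chrom, start, start + 22, "+")
                counts = [int(rng.integers(0, min(mx, 19) + 1)) for _ in range(n_samples)]
                counts[int(rng.integers(n_samples))] = mx
                cid = f"grid{i:03d}"
                candidates.append(
                    MiRNACandidate(
                        candidate_id=cid,
                        score=float(score),
                        hairpin_interval=hairpin,
                        mature_interval=mature,
                        arm="5p",
                        mature_sequence=_random_rna(rng, 22),
                        read_counts=tuple(counts),
                    )
                )
                rows.append(
                    {"id": cid, "score": score, "max_reads": mx,
                     "passes_filter": score >= 1.0 and mx >= 20}
                )
                i += 1
    return candidates, pd.DataFrame(rows).set_index("id")


# ---------------------------------------------------------------------------
# Ortholog sets
# ---------------------------------------------------------------------------

def generate_ortholog_set(
    mature_sequence: str,
    mismatch_spec: Mapping[str, Sequence[int]],
    flank: int = 30,
    seed: int = 0,
    mir_id: str = "mir",
    panel: Sequence[str] = DEFAULT_PANEL,
) -> SpeciesSequenceSet:
    """Embed a mutated copy of the mature sequence in random flanks per species.

    ``mismatch_spec`` lists, per species, the 1-based mature positions to
    mutate (to a different base, uniformly chosen).  Species missing from
    the spec get the exact sequence; the human spec must be empty so the
    human region contains the exact mature sequence.
    """
    rng = np.random.default_rng(seed)
    mature = mature_sequence.upper().replace("T", "U")
    n = len(mature)
    for species, positions in mismatch_spec.items():
        for pos in positions:
            if not 1 <= pos <= n:
                raise ValueError(
                    f"{species}: mismatch position {pos} outside 1..{n}"
                )
    if mismatch_spec.get("human"):
        raise ValueError("the human region must carry the exact mature sequence")
    regions = {}
    for species in panel:
        seq = list(mature)
        for pos in mismatch_spec.get(species, ()):  # 1-based
            old = seq[pos - 1]
            seq[pos - 1] = str(rng.choice([b for b in "ACGU" if b != old]))
        left = _random_rna(rng, flank)
        right = _random_rna(rng, flank)
        regions[species] = left + "".join(seq) + right
    return SpeciesSequenceSet(
        mir_id=mir_id, mature_sequence=mature, regions=regions, panel=tuple(panel)
    )


def simulate_conservation_cohort(
    candidates: Sequence[MiRNACandidate],
    truth_table: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[list[SpeciesSequenceSet], dict[str, frozenset[str]]]:
    """Ortholog sets per candidate: known ones broadly conserved, putative
    ones primate-only (seed mismatches planted in the non-primates).

    Returns the sets and the truth mapping candidate id -> species in
    which the planted mismatches satisfy the seed-aware rule.
    """
    rng = _rng(config, stage=4)
    sets, truth = [], {}
    seed_pos = sorted(seed_positions(22))
    nonseed_pos = [p for p in range(1, 23) if p not in seed_pos]
    for candidate in candidates:
        status = truth_table.loc[candidate.candidate_id, "status"]
        spec: dict[str, list[int]] = {"human": []}
        conserved = {"human", "chimp", "rhesus"}
        spec["chimp"] = []
        spec["rhesus"] = [int(rng.choice(nonseed_pos))]  # 1 non-seed mm: still conserved
        if status == "known":
            spec["dog"] = []
            spec["mouse"] = [int(rng.choice(nonseed_pos))]
            spec["zebrafish"] = [int(rng.choice(seed_pos))]  # seed mm: not conserved
            conserved |= {"dog", "mouse"}
        else:
            for species in ("dog", "mouse", "zebrafish"):
                mm = [int(rng.choice(seed_pos))]
                mm.append(int(rng.choice([p for p in nonseed_pos if p not in mm])))
                spec[species] = mm
        sets.append(
            generate_ortholog_set(
                candidate.mature_sequence,
                spec,
                flank=config.ortholog_flank,
                seed=int(rng.integers(2**31)),
                mir_id=candidate.candidate_id,
            )
        )
        truth[candidate.candidate_id] = frozenset(conserved)
    return sets, truth


# ---------------------------------------------------------------------------
# Co-expression loci
# ---------------------------------------------------------------------------

def simulate_coexpression(
    genome: SyntheticGenome, config: SimulationConfig | None = None
) -> tuple[list[LongTranscriptCall], list[MiRNACandidate], pd.DataFrame]:
    """Long transcripts over pre-miRNA hairpins in both span geometries.

    Each planted spec (pattern, coverage, mirna_expressed) takes one
    locus, preferring a cluster member for the first FIVE_PRIME_ONLY spec
    so the miR-144/451-like arrangement is exercised.  Coverage is
    constant across samples, so mean, min and sum aggregation agree up to
    the sample count.  Candidates at expressed loci pass the retention
    filter; at decoy loci they fail the score threshold.
    """
    config = config or genome.config
    rng = _rng(config, stage=5)
    cluster = set(genome.truth.cluster_loci[0]) if genome.truth.cluster_loci else set()
    available = [l for l in genome.pre_mirna_loci]
    # deterministic assignment: first FIVE_PRIME_ONLY spec goes to a cluster locus
    assignment: list[PreMiRNALocus] = []
    used: set[str] = set()
    for pattern, _cov, _expr in config.planted_coexpression:
        pick = None
        if pattern == "FIVE_PRIME_ONLY" and cluster - used:
            pick = next(l for l in available if l.locus_id in cluster and l.locus_id not in used)
        else:
            pick = next(l for l in available if l.locus_id not in used and l.locus_id not in cluster)
        used.add(pick.locus_id)
        assignment.append(pick)

    transcripts, mirnas, rows = [], [], []
    flank = config.coexpression_flank
    for (pattern, coverage, expressed), locus in zip(config.planted_coexpression, assignment):
        hp = locus.hairpin
        if pattern == "FULL_SPAN":
            interval = GenomicInterval(
                hp.chrom, max(0, hp.start - flank - 40), hp.end + flank + 40, hp.strand
            )
        elif pattern == "FIVE_PRIME_ONLY":
            ext = int(rng.integers(120, 180))
            if hp.strand == "+":
                interval = GenomicInterval(
                    hp.chrom, max(0, hp.start - ext), locus.loop.end, hp.strand
                )
            else:
                interval = GenomicInterval(hp.chrom, locus.loop.start, hp.end + ext, hp.strand)
        else:
            raise ConfigurationError(f"unsupported planted pattern {pattern!r}")
        tx_id = f"lnc-{locus.locus_id}"
        transcripts.append(
            LongTranscriptCall(
                transcript_id=tx_id,
                interval=interval,
                support=tuple([coverage] * config.n_samples),
            )
        )
        mat = GenomicInterval(
            hp.chrom, locus.arm5p.start, locus.arm5p.start + 22, hp.strand
        )
        mirnas.append(
            MiRNACandidate(
                candidate_id=f"cocand-{locus.locus_id}",
                score=2.0 if expressed else 0.5,
                hairpin_interval=hp,
                mature_interval=mat,
                arm="5p",
                mature_sequence=_random_rna(rng, 22),
                read_counts=tuple(
                    [100] * config.n_short_samples if expressed else [5] * config.n_short_samples
                ),
            )
        )
        rows.append(
            {
                "locus_id": locus.locus_id,
                "transcript_id": tx_id,
                "pattern": pattern,
                "coverage": coverage,
                "mirna_expressed": expressed,
            }
        )
    truth = pd.DataFrame(rows).set_index("locus_id")
    genome.truth.coexpression = truth
    return transcripts, mirnas, truth
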