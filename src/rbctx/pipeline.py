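"""End-to-end orchestration: simulate -> census -> locdist -> gsea ->
mirna -> conserve -> jointlocus, from a single config.

Every stage reads and writes plain-text artifacts (GTF, BED6, TSV,
FASTA) under one output directory, and the run returns a manifest of
sha256 content hashes so that identical config + seed provably produce
identical outputs.  Stage parameters default to the study's stated
values: RPKM threshold 0.5, 10 kb proximal window, miRDeep score >= 1
with >= 20 reads in one sample, top-500 gene set, coverage floor 50.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import census as census_mod
from . import conservation as cons_mod
from . import gsea as gsea_mod
from . import joint_locus as joint_mod
from . import mirna_catalog as cat_mod
from . import synthetic_data as sim_mod
from .genome_model import GenomicInterval, read_annotation, read_bed, write_annotation, write_bed

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]

log = logging.getLogger("rbctx.pipeline")


class PipelineError(RuntimeError):
    """A stage cannot run; the message names the stage and the missing input."""


@dataclass
class PipelineConfig:
    out_dir: str = "rbctx_run"
    run_mode: str = "full"  # simulate | analyze | full
    seed: int = 0
    simulation: sim_mod.SimulationConfig = field(default_factory=sim_mod.SimulationConfig)
    rpkm_threshold: float = 0.5
    proximal_window: int = 10_000
    top_k: int = 500
    n_perm: int = 1000
    gsea_weight: float = 1.0
    min_score: float = 1.0
    min_reads: int = 20
    coverage_min: float = 50.0
    flank: int = 10
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        if seed is not None:
            raw["seed"] = seed
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(sim_mod.SimulationConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise PipelineError(f"unknown simulation keys: {sorted(sim_unknown)}")
        config = cls(simulation=sim_mod.SimulationConfig(**sim_raw), **raw)
        return config


def validate_config(config: PipelineConfig) -> list[str]:
    """Violation messages; empty when the config satisfies every invariant."""
    problems = config.simulation.validate()
    if config.rpkm_threshold < 0:
        problems.append("rpkm_threshold must be >= 0")
    if config.proximal_window < 0:
        problems.append("proximal_window must be >= 0")
    if config.top_k < 1:
        problems.append("top_k must be >= 1")
    if config.n_perm < 1:
        problems.append("n_perm must be >= 1")
    if config.min_reads < 0:
        problems.append("min_reads must be >= 0")
    if config.coverage_min < 0:
        problems.append("coverage_min must be >= 0")
    if config.aggregation not in ("mean", "min", "sum"):
        problems.append("aggregation must be mean|min|sum")
    if config.run_mode not in ("simulate", "analyze", "full"):
        problems.append("run_mode must be simulate|analyze|full")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(stage: str, path: Path) -> Path:
    if not path.exists():
        raise PipelineError(f"stage '{stage}': missing input {path}")
    return path


def _write_matrix(matrix: census_mod.ExpressionMatrix, out: Path, prefix: str) -> list[Path]:
    paths = []
    p = out / f"{prefix}_counts.tsv"
    matrix.counts.astype(int).rename_axis("gene").to_csv(p, sep="\t")
    paths.append(p)
    p = out / f"{prefix}_lengths.tsv"
    matrix.exonic_length.rename("exonic_length").rename_axis("gene").to_csv(p, sep="\t")
    paths.append(p)
    p = out / f"{prefix}_library_sizes.tsv"
    matrix.library_size.rename("library_size").rename_axis("sample").to_csv(p, sep="\t")
    paths.append(p)
    return paths


def _read_matrix(out: Path, prefix: str, stage: str) -> census_mod.ExpressionMatrix:
    counts = pd.read_csv(
        _require(stage, out / f"{prefix}_counts.tsv"), sep="\t", index_col="gene"
    )
    lengths = pd.read_csv(
        _require(stage, out / f"{prefix}_lengths.tsv"), sep="\t", index_col="gene"
    )["exonic_length"]
    lib = pd.read_csv(
        _require(stage, out / f"{prefix}_library_sizes.tsv"), sep="\t", index_col="sample"
    )["library_size"]
    return census_mod.ExpressionMatrix(counts=counts, exonic_length=lengths, library_size=lib)


def comparator_levels(
    genome: sim_mod.SyntheticGenome, rng_seed: int, correlated: bool
) -> dict[str, float]:
    """Expression profile for a comparator cell type.

    ``correlated=True`` jitters the erythrocyte profile (an erythroid
    progenitor-like condition, so the top erythrocyte genes stay high);
    otherwise an independent profile (a PBMC-like condition).
    """
    import numpy as np

    rng = np.random.default_rng(rng_seed)
    levels = {}
    for gene in genome.genes:
        base = genome.truth.expression_level[gene.gene_id]
        if correlated:
            level = base * float(rng.lognormal(0.0, 0.25))
            if base == 0 and rng.random() < 0.6:
                level = float(rng.lognormal(2.0, 1.0))
        else:
            level = float(rng.lognormal(3.0, 1.0)) if rng.random() < 0.75 else 0.0
        levels[gene.gene_id] = level
    return levels


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; return the manifest.

    The manifest maps each artifact path (relative to ``out_dir``) to its
    sha256 hash and is itself written as ``manifest.json``.
    """
    problems = validate_config(config)
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    simulate = config.run_mode in ("simulate", "full")
    analyze = config.run_mode in ("analyze", "full")

    if simulate:
        log.info("stage=simulate seed=%d", config.seed)
        genome = sim_mod.generate_genome(config.simulation)
        write_annotation(genome.genes, out / "annotation.gtf")
        artifacts.append(out / "annotation.gtf")
        loci_rows = []
        for locus in genome.pre_mirna_loci:
            loci_rows.append(
                [locus.locus_id, locus.hairpin.chrom, locus.hairpin.start, locus.hairpin.end,
                 locus.strand, locus.arm5p.start, locus.arm5p.end,
                 locus.loop.start, locus.loop.end, locus.arm3p.start, locus.arm3p.end]
            )
        pd.DataFrame(
            loci_rows,
            columns=["locus_id", "chrom", "start", "end", "strand",
                     "arm5p_start", "arm5p_end", "loop_start", "loop_end",
                     "arm3p_start", "arm3p_end"],
        ).to_csv(out / "pre_mirna_loci.tsv", sep="\t", index=False)
        artifacts.append(out / "pre_mirna_loci.tsv")

        reads, rbc_matrix, _ = sim_mod.simulate_reads(genome, sample_prefix="RBC")
        bed_records = [(iv, name) for placements in reads.values() for iv, name in placements]
        write_bed(bed_records, out / "reads.bed")
        artifacts.append(out / "reads.bed")
        artifacts += _write_matrix(rbc_matrix, out, "rbc")
        for prefix, correlated in (("d8", True), ("pbmc", False)):
            levels = comparator_levels(genome, rng_seed=config.seed + (7 if correlated else 11),
                                        correlated=correlated)
            _, matrix, _ = sim_mod.simulate_reads(
                genome, expression_override=levels, sample_prefix=prefix.upper()
            )
            artifacts += _write_matrix(matrix, out, prefix)

        candidates, truth_table = sim_mod.simulate_mirna_candidates(genome)
        sample_ids = [f"SR{i + 1}" for i in range(config.simulation.n_short_samples)]
        cat_mod.write_candidates(candidates, out / "mirna_candidates.tsv", sample_ids)
        artifacts.append(out / "mirna_candidates.tsv")
        ref_rows = [
            [r.mir_id, r.mature_sequence, r.hairpin_interval.chrom,
             r.hairpin_interval.start, r.hairpin_interval.end, r.hairpin_interval.strand,
             r.mature_interval.start, r.mature_interval.end]
            for r in genome.reference_mirnas
        ]
        pd.DataFrame(
            ref_rows,
            columns=["mir_id", "sequence", "chrom", "hp_start", "hp_end", "strand",
                     "mat_start", "mat_end"],
        ).to_csv(out / "reference_mirnas.tsv", sep="\t", index=False)
        artifacts.append(out / "reference_mirnas.tsv")

        sets, _cons_truth = sim_mod.simulate_conservation_cohort(
            candidates, truth_table, config.simulation
        )
        fasta = {}
        for s in sets:
            for species, region in s.regions.items():
                fasta[f"{species}|{s.mir_id}"] = region
        from .genome_model import write_fasta

        write_fasta(fasta, out / "ortholog_regions.fasta")
        artifacts.append(out / "ortholog_regions.fasta")
        (out / "mature_queries.tsv").write_text(
            "mir_id\tsequence\n"
            + "".join(f"{s.mir_id}\t{s.mature_sequence}\n" for s in sets)
        )
        artifacts.append(out / "mature_queries.tsv")

        transcripts, co_mirnas, _ = sim_mod.simulate_coexpression(genome)
        tx_rows = [
            [t.transcript_id, t.interval.chrom, t.interval.start, t.interval.end,
             t.strand, *t.support]
            for t in transcripts
        ]
        pd.DataFrame(
            tx_rows,
            columns=["transcript_id", "chrom", "start", "end", "strand"]
            + [f"S{i + 1}" for i in range(config.simulation.n_samples)],
        ).to_csv(out / "long_transcripts.tsv", sep="\t", index=False)
        artifacts.append(out / "long_transcripts.tsv")
        cat_mod.write_candidates(co_mirnas, out / "coexpression_candidates.tsv", sample_ids)
        artifacts.append(out / "coexpression_candidates.tsv")

    if analyze:
        # census
        log.info("stage=census threshold=%.3g", config.rpkm_threshold)
        genes = read_annotation(_require("census", out / "annotation.gtf"))
        rbc_matrix = _read_matrix(out, "rbc", "census")
        result = census_mod.run_census(rbc_matrix, config.rpkm_threshold)
        result.rpkm.rename_axis("gene").to_csv(out / "rpkm.tsv", sep="\t")
        artifacts.append(out / "rpkm.tsv")
        pd.DataFrame(
            {
                "gene": sorted(rbc_matrix.gene_ids),
                "expressed_any": [g in result.expressed_any for g in sorted(rbc_matrix.gene_ids)],
                "expressed_all": [g in result.expressed_all for g in sorted(rbc_matrix.gene_ids)],
            }
        ).to_csv(out / "census.tsv", sep="\t", index=False)
        artifacts.append(out / "census.tsv")

        # location distribution
        log.info("stage=locdist window=%d", config.proximal_window)
        bed = read_bed(_require("locdist", out / "reads.bed"))
        by_sample: dict[str, list[GenomicInterval]] = {}
        for iv, name in bed:
            by_sample.setdefault(name.split(":")[0], []).append(iv)
        dist = census_mod.read_location_distribution(
            by_sample, genes, proximal_window=config.proximal_window
        )
        dist.fractions.rename_axis("category").to_csv(out / "location_distribution.tsv", sep="\t")
        artifacts.append(out / "location_distribution.tsv")

        # gsea
        log.info("stage=gsea top_k=%d n_perm=%d", config.top_k, config.n_perm)
        d8 = _read_matrix(out, "d8", "gsea")
        pbmc = _read_matrix(out, "pbmc", "gsea")
        ranked = gsea_mod.rank_by_log2fc(d8, pbmc)
        k = min(config.top_k, max(1, len(rbc_matrix.gene_ids) // 4))
        gene_set = gsea_mod.top_k_gene_set(census_mod.compute_rpkm(rbc_matrix), k)
        gres = gsea_mod.gsea_permutation_p(
            ranked, gene_set, n_perm=config.n_perm, seed=config.seed,
            weight_exponent=config.gsea_weight,
        )
        pd.DataFrame(
            [{"k": k, "es": gres.es, "nes": gres.nes, "p_value": gres.p_value,
              "n_leading_edge": len(gres.leading_edge)}]
        ).to_csv(out / "gsea.tsv", sep="\t", index=False)
        artifacts.append(out / "gsea.tsv")
        pd.Series(gres.running_sum, name="running_sum").rename_axis("position").to_csv(
            out / "gsea_running_sum.tsv", sep="\t"
        )
        artifacts.append(out / "gsea_running_sum.tsv")

        # mirna catalog
        log.info("stage=mirna min_score=%.3g min_reads=%d", config.min_score, config.min_reads)
        candidates, sample_ids = cat_mod.read_candidates(
            _require("mirna", out / "mirna_candidates.tsv")
        )
        ref_frame = pd.read_csv(_require("mirna", out / "reference_mirnas.tsv"), sep="\t")
        from .genome_model import ReferenceMiRNA

        reference = [
            ReferenceMiRNA(
                mir_id=row.mir_id,
                mature_sequence=row.sequence,
                mature_interval=GenomicInterval(row.chrom, row.mat_start, row.mat_end, row.strand),
                hairpin_interval=GenomicInterval(row.chrom, row.hp_start, row.hp_end, row.strand),
            )
            for row in ref_frame.itertuples(index=False)
        ]
        entries = cat_mod.build_catalog(
            candidates, reference, genes,
            min_score=config.min_score, min_reads=config.min_reads,
        )
        pd.DataFrame(
            [{"id": e.candidate.candidate_id, "status": e.status, "location": e.location,
              "score": e.candidate.score, "max_reads": e.candidate.max_reads}
             for e in entries]
        ).to_csv(out / "mirna_catalog.tsv", sep="\t", index=False)
        artifacts.append(out / "mirna_catalog.tsv")
        summaries = cat_mod.summarize_catalog(entries, sample_ids)
        summaries["location_pct"].to_csv(out / "mirna_location_pct.tsv", sep="\t")
        artifacts.append(out / "mirna_location_pct.tsv")
        summaries["top10_read_pct"].to_csv(out / "mirna_top10_read_pct.tsv", sep="\t")
        artifacts.append(out / "mirna_top10_read_pct.tsv")

        # conservation
        log.info("stage=conserve panel=%s", ",".join(cons_mod.DEFAULT_PANEL))
        from .genome_model import read_fasta

        regions_fasta = read_fasta(_require("conserve", out / "ortholog_regions.fasta"))
        queries = pd.read_csv(
            _require("conserve", out / "mature_queries.tsv"), sep="\t"
        )
        status_by_id = {
            c.candidate_id: cat_mod.classify_known_putative(c, reference)
            for c in candidates
        }
        calls_by_status: dict[str, list[cons_mod.ConservationCall]] = {}
        call_rows = []
        for row in queries.itertuples(index=False):
            regions = {
                sp: regions_fasta[f"{sp}|{row.mir_id}"]
                for sp in cons_mod.DEFAULT_PANEL
                if f"{sp}|{row.mir_id}" in regions_fasta
            }
            if len(regions) < len(cons_mod.DEFAULT_PANEL):
                continue
            sset = cons_mod.SpeciesSequenceSet(
                mir_id=row.mir_id, mature_sequence=row.sequence, regions=regions
            )
            call = cons_mod.conservation_call(sset)
            status = status_by_id.get(row.mir_id, "putative")
            calls_by_status.setdefault(status, []).append(call)
            call_rows.append(
                {"mir_id": row.mir_id, "status": status,
                 "species_count": call.species_count, "bin": call.bin,
                 "primate_only": call.primate_only,
                 "conserved_in": ",".join(sorted(call.conserved_in))}
            )
        pd.DataFrame(call_rows).to_csv(out / "conservation_calls.tsv", sep="\t", index=False)
        artifacts.append(out / "conservation_calls.tsv")
        cons_mod.summarize_conservation(calls_by_status).to_csv(
            out / "conservation_summary.tsv", sep="\t"
        )
        artifacts.append(out / "conservation_summary.tsv")

        # joint locus
        log.info("stage=jointlocus coverage_min=%.3g agg=%s", config.coverage_min,
                 config.aggregation)
        tx_frame = pd.read_csv(_require("jointlocus", out / "long_transcripts.tsv"), sep="\t")
        support_cols = [c for c in tx_frame.columns
                        if c not in ("transcript_id", "chrom", "start", "end", "strand")]
        transcripts = [
            joint_mod.LongTranscriptCall(
                transcript_id=row.transcript_id,
                interval=GenomicInterval(row.chrom, row.start, row.end, row.strand),
                support=tuple(int(getattr(row, c)) for c in support_cols),
            )
            for row in tx_frame.itertuples(index=False)
        ]
        loci_frame = pd.read_csv(_require("jointlocus", out / "pre_mirna_loci.tsv"), sep="\t")
        from .genome_model import PreMiRNALocus

        loci = [
            PreMiRNALocus(
                locus_id=row.locus_id,
                hairpin=GenomicInterval(row.chrom, row.start, row.end, row.strand),
                arm5p=GenomicInterval(row.chrom, row.arm5p_start, row.arm5p_end, row.strand),
                loop=GenomicInterval(row.chrom, row.loop_start, row.loop_end, row.strand),
                arm3p=GenomicInterval(row.chrom, row.arm3p_start, row.arm3p_end, row.strand),
            )
            for row in loci_frame.itertuples(index=False)
        ]
        co_candidates, _ = cat_mod.read_candidates(
            _require("jointlocus", out / "coexpression_candidates.tsv")
        )
        retained = cat_mod.filter_candidates(
            co_candidates, config.min_score, config.min_reads
        )
        pairs = joint_mod.find_spanning_transcripts(transcripts, loci)
        calls = joint_mod.call_coexpression_loci(
            pairs, retained, coverage_min=config.coverage_min,
            aggregation=config.aggregation, flank=config.flank,
        )
        pd.DataFrame(
            [{"locus_id": c.locus_id, "transcript_id": c.transcript_id,
              "pattern": c.pattern, "coverage": c.locus_coverage}
             for c in calls]
        ).to_csv(out / "coexpression_loci.tsv", sep="\t", index=False)
        artifacts.append(out / "coexpression_loci.tsv")
        joint_mod.render_locus_report(calls, transcripts, loci).to_csv(
            out / "locus_report.tsv", sep="\t", index=False
        )
        artifacts.append(out / "locus_report.tsv")

    manifest = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
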