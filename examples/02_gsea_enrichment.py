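"""GSEA: is the top erythrocyte gene set enriched in a progenitor-like
versus an unrelated comparator ranking?

Builds an erythrocyte-correlated condition (D8-like) and an independent
condition (PBMC-like), ranks genes by log2 fold change of mean RPKM, and
tests the top erythrocyte genes with a gene-label permutation null.
"""

from rbctx.census import compute_rpkm
from rbctx.gsea import gsea_permutation_p, rank_by_log2fc, top_k_gene_set
from rbctx.pipeline import comparator_levels
from rbctx.synthetic_data import SimulationConfig, generate_genome, simulate_reads

genome = generate_genome(SimulationConfig(seed=42))
_, rbc, _ = simulate_reads(genome)
_, d8, _ = simulate_reads(
    genome, expression_override=comparator_levels(genome, 7, correlated=True),
    sample_prefix="D8",
)
_, pbmc, _ = simulate_reads(
    genome, expression_override=comparator_levels(genome, 11, correlated=False),
    sample_prefix="PBMC",
)

ranked = rank_by_log2fc(d8, pbmc)
gene_set = top_k_gene_set(compute_rpkm(rbc), k=50)
result = gsea_permutation_p(ranked, gene_set, n_perm=1000, seed=42)

print(f"ES  = {result.es:.3f}   (signed extremum of the running sum)")
print(f"NES = {result.nes:.3f}   (ES / mean same-sign null magnitude)")
print(f"p   = {result.p_value:.4g}  over {result.n_perm} label permutations")
print(f"leading edge: {len(result.leading_edge)} genes")
# a positive ES with small p says the top erythrocyte genes sit high in
# the D8/PBMC ranking: the progenitor-like condition carries the signature
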