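"""Expressed-transcript census on a simulated erythrocyte cohort.

Generates a toy genome with ~200 genes (half planted as expressed),
places 10,000 reads per sample for 3 samples, then runs the RPKM >= 0.5
census and the read genomic-location breakdown.
"""

from rbctx.census import read_location_distribution, run_census, top_n_by_mean
from rbctx.synthetic_data import SimulationConfig, generate_genome, simulate_reads

genome = generate_genome(SimulationConfig(seed=42))
reads, matrix, truth = simulate_reads(genome)

census = run_census(matrix, threshold=0.5)
n_true = sum(truth.gene_expressed.values())
print(f"genes: {len(genome.genes)}, planted expressed: {n_true}")
print(f"expressed in >=1 sample: {len(census.expressed_any)}")
print(f"expressed in all samples: {len(census.expressed_all)}")
# the two counts bracket the planted truth: RPKM >= 0.5 in at least one
# sample is the study's inclusion rule, 'all samples' is the stricter census

top = top_n_by_mean(census.rpkm, 5)
print("\ntop 5 by mean RPKM (rank, gene, value):")
for row in top.itertuples(index=False):
    print(f"  {row.rank}  {row.gene}  {row.value:.1f}")

by_sample = {s: [iv for iv, _ in r] for s, r in reads.items()}
dist = read_location_distribution(by_sample, genome.genes)
print("\nmean compartment fractions (planted 0.93/0.04/0.02/0.01):")
print(dist.mean_fractions.round(4).to_string())
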