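"""miRNA catalog: filter miRDeep-style candidates, split known/putative,
classify genomic location, summarize abundance.

Retention uses the discovery cutoffs (score >= 1 and >= 20 reads in at
least one of five samples); known status needs an exact mature-sequence
match or a same-strand hairpin overlap with the reference set.
"""

from rbctx.mirna_catalog import build_catalog, filter_candidates, summarize_catalog
from rbctx.synthetic_data import SimulationConfig, generate_genome, simulate_mirna_candidates

genome = generate_genome(SimulationConfig(seed=42))
candidates, truth = simulate_mirna_candidates(genome)

retained = filter_candidates(candidates)
print(f"candidates: {len(candidates)}, retained by score/read filter: {len(retained)}")

entries = build_catalog(candidates, genome.reference_mirnas, genome.genes)
for e in entries:
    print(f"  {e.candidate.candidate_id}: {e.status}, {e.location}, "
          f"score {e.candidate.score}, max reads {e.candidate.max_reads}")

tables = summarize_catalog(entries)
print("\nlocation percentages by status (rows sum to 100):")
print(tables["location_pct"].round(1).to_string())
print("\ntop miRNAs, per-sample read % of known mature reads:")
print(tables["top10_read_pct"].round(2).to_string())
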