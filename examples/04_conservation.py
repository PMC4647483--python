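"""Seed-aware conservation across the six-species vertebrate panel.

A mature miRNA is conserved in a species when its orthologous region
holds an ungapped window with zero mismatches in the seed (positions
2-8) and at most one mismatch elsewhere.  Putative erythrocyte miRNAs
tend to be primate-only; known ones reach the non-primates.
"""

from rbctx.conservation import conservation_call, summarize_conservation
from rbctx.synthetic_data import (
    SimulationConfig,
    generate_genome,
    generate_ortholog_set,
    simulate_conservation_cohort,
    simulate_mirna_candidates,
)

# single query: seed mismatches planted in the non-primates
mature = "ACGUACGUACGUACGUACGUAC"
sset = generate_ortholog_set(
    mature, {"dog": [3], "mouse": [4, 12], "zebrafish": [2, 5]}, flank=30, seed=1
)
call = conservation_call(sset)
print(f"conserved in {call.species_count} species: {sorted(call.conserved_in)}")
print(f"bin {call.bin}, primate_only={call.primate_only}")
# seed hits in dog/mouse/zebrafish leave only the primates: primate-only

# cohort: known candidates broadly conserved, putative ones primate-only
config = SimulationConfig(seed=42)
genome = generate_genome(config)
candidates, truth = simulate_mirna_candidates(genome)
sets, _ = simulate_conservation_cohort(candidates, truth, config)
calls = {"known": [], "putative": []}
for s in sets:
    calls[truth.loc[s.mir_id, "status"]].append(conservation_call(s))
print("\ncohort summary (% per species-count bin and primate-only):")
print(summarize_conservation(calls).round(1).to_string())
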